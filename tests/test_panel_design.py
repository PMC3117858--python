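"""Eligibility, 25-class priority, spacing plans and greedy selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rrlchip.panel_design import (
    DEFAULT_PRIORITY_TABLE,
    CandidateSnp,
    PriorityTable,
    SpacingPlan,
    assemble_manifest,
    assign_priority,
    classify_infinium,
    eligible,
    flag_neighbors,
    select_panel,
    spacing_distribution,
    spacing_plan,
)


def cand(i, pos, chrom="chr1", alleles=("A", "G"), score=1.0, **kw):
    return CandidateSnp(f"snp{i}", chrom, pos, alleles, score, **kw)


class TestInfinium:
    @pytest.mark.parametrize("pair", [("A", "G"), ("A", "C"), ("T", "C"), ("T", "G")])
    def test_single_bead_pairs_are_type_ii(self, pair):
        assert classify_infinium(pair) == "II"

    @pytest.mark.parametrize("pair", [("A", "T"), ("C", "G")])
    def test_complement_ambiguous_pairs_are_type_i(self, pair):
        assert classify_infinium(pair) == "I"

    def test_exactly_four_of_six_pairs_are_type_ii(self):
        pairs = list(itertools.combinations("ACGT", 2))
        assert len(pairs) == 6
        assert sum(classify_infinium(p) == "II" for p in pairs) == 4

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            classify_infinium(("A", "A"))


class TestNeighborFlagging:
    def _flags(self, cand_pos, all_pos):
        cands = [cand(i, p) for i, p in enumerate(cand_pos)]
        out = flag_neighbors(cands, {"chr1": all_pos})
        return [c.neighbor_excluded for c in out]

    def test_variants_five_bp_apart_both_flagged(self):
        assert self._flags([100, 105], [100, 105]) == [True, True]

    def test_variants_eleven_bp_apart_not_flagged(self):
        assert self._flags([100, 111], [100, 111]) == [False, False]

    def test_boundary_at_exactly_ten_bp(self):
        assert self._flags([100, 110], [100, 110]) == [True, True]

    def test_lone_variant_not_flagged(self):
        assert self._flags([100], [100]) == [False]

    def test_other_chromosome_does_not_count(self):
        cands = [cand(0, 100, chrom="chr1")]
        out = flag_neighbors(cands, {"chr2": [100, 105]})
        assert not out[0].neighbor_excluded


class TestPriority:
    def test_validated_high_maf_is_class_one(self):
        c = cand(0, 1, score=0.9, validated=True, source="known_db",
                 maf_broiler=0.45, maf_layer=0.41)
        assert assign_priority(c) == 1

    def test_known_db_without_maf_is_class_25(self):
        c = cand(0, 1, score=0.9, validated=False, source="known_db")
        assert assign_priority(c) == 25

    def test_ineligible_candidate_rejected(self):
        c = cand(0, 1, alleles=("A", "T"), score=0.9)
        with pytest.raises(ValueError):
            assign_priority(c)

    def test_lattice_partition_hits_all_25_classes(self):
        table = DEFAULT_PRIORITY_TABLE
        mafs = [0.45, 0.35, 0.25, 0.15, 0.05, None]
        seen = set()
        for validated in (True, False):
            for source in ("known_db", "rrl_novel", "rrl_and_db"):
                for mb in mafs:
                    for ml in mafs:
                        try:
                            c = cand(0, 1, score=0.9, validated=validated,
                                     source=source, maf_broiler=mb, maf_layer=ml)
                        except ValueError:
                            continue
                        k = table.priority_class(c)
                        assert 1 <= k <= 25
                        seen.add(k)
        assert seen == set(range(1, 26))

    def test_design_score_boundary(self):
        assert eligible(cand(0, 1, score=0.6))
        assert not eligible(cand(0, 1, score=0.59))


class TestSpacingPlan:
    def test_macro_and_micro_targets(self):
        plan = spacing_plan({"c1": "macro", "c2": "micro"})
        assert plan["c1"] == 20_000 and plan["c2"] == 4_000

    def test_intermediates_monotone_between_bounds(self):
        plan = spacing_plan(
            {"c1": "macro", "c2": "intermediate", "c3": "intermediate", "c4": "micro"},
            chromosome_lengths={"c2": 5_000_000, "c3": 1_000_000},
        )
        assert plan["c1"] > plan["c2"] >= plan["c3"] > plan["c4"]

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            spacing_plan({"c1": "mito"})


class TestSelectPanel:
    def test_empty_candidates_empty_selection(self):
        selected, gaps = select_panel([], SpacingPlan({"chr1": 20_000}))
        assert selected == []

    def test_greedy_walk_matches_stated_rule(self):
        # brute-force replay: spacing 20 kb, window (cursor+10k, cursor+30k]
        class ByClass:
            def priority_class(self, c):
                return {5_000: 3, 18_000: 1, 22_000: 2, 39_000: 1, 41_000: 5}[c.pos]

        cands = [cand(i, p) for i, p in enumerate([5_000, 18_000, 22_000, 39_000, 41_000])]
        selected, _ = select_panel(cands, SpacingPlan({"chr1": 20_000}), ByClass())
        assert [c.pos for c in selected] == [18_000, 39_000]

    def test_uniform_class_shift_leaves_selection_unchanged(self):
        base = {5_000: 3, 18_000: 1, 22_000: 2, 39_000: 1, 41_000: 5}

        class Shifted:
            def __init__(self, f):
                self.f = f

            def priority_class(self, c):
                return self.f(base[c.pos])

        cands = [cand(i, p) for i, p in enumerate(base)]
        plan = SpacingPlan({"chr1": 20_000})
        ref = [c.pos for c in select_panel(cands, plan, Shifted(lambda k: k))[0]]
        doubled = [c.pos for c in select_panel(cands, plan, Shifted(lambda k: 2 * k))[0]]
        assert ref == doubled

    def test_gap_recorded_when_window_empty(self):
        cands = [cand(0, 1_000), cand(1, 90_000)]
        _, gaps = select_panel(cands, SpacingPlan({"chr1": 20_000}))
        assert gaps["chr1"] > 0

    def test_ineligible_input_rejected(self):
        with pytest.raises(ValueError):
            select_panel([cand(0, 1, score=0.2)], SpacingPlan({"chr1": 20_000}))

    def test_selection_is_deterministic(self):
        rng = np.random.default_rng(3)
        cands = sorted(
            (
                cand(i, int(p), score=0.9, maf_broiler=0.3, maf_layer=0.3)
                for i, p in enumerate(rng.integers(0, 200_000, 300))
            ),
            key=lambda c: c.pos,
        )
        plan = SpacingPlan({"chr1": 20_000})
        a = [c.id for c in select_panel(cands, plan)[0]]
        b = [c.id for c in select_panel(cands, plan)[0]]
        assert a == b

    def test_improving_a_selected_candidates_class_keeps_it(self):
        rng = np.random.default_rng(4)
        positions = np.sort(rng.integers(0, 100_000, 60))
        mafs = [0.45, 0.35, 0.25, 0.15]
        cands = [
            cand(i, int(p), score=0.9, source="rrl_novel",
                 maf_broiler=mafs[i % 4], maf_layer=mafs[(i // 4) % 4])
            for i, p in enumerate(positions)
        ]
        plan = SpacingPlan({"chr1": 10_000})
        selected = select_panel(cands, plan)[0]
        victim = selected[1]
        improved = [
            CandidateSnp(c.id, c.chrom, c.pos, c.alleles, c.design_score,
                         validated=True, source=c.source,
                         maf_broiler=0.45, maf_layer=0.45)
            if c.id == victim.id
            else c
            for c in cands
        ]
        new_ids = {c.id for c in select_panel(improved, plan)[0]}
        assert victim.id in new_ids

    def test_median_gap_tracks_plan_when_candidates_dense(self):
        rng = np.random.default_rng(5)
        positions = np.sort(rng.choice(400_000, size=2_000, replace=False))
        cands = [cand(i, int(p), score=0.9) for i, p in enumerate(positions)]
        plan = SpacingPlan({"chr1": 20_000})
        selected = select_panel(cands, plan)[0]
        gaps = np.diff([c.pos for c in selected])
        assert abs(np.median(gaps) - 20_000) <= 5_000


class TestManifest:
    def test_total_is_sum_of_categories(self):
        chrom_sel = [cand(i, 1_000 * i, score=0.9) for i in range(10)]
        addons = {
            "unplaced_contig": [cand(100 + i, i, chrom="contig1") for i in range(3)],
            "chr_random": [cand(200, 5, chrom="chr1_random")],
            "mito": [cand(300, 5, chrom="chrMT", alleles=("A", "T"))],
        }
        manifest = assemble_manifest(chrom_sel, addons)
        counts = manifest.category_counts()
        assert manifest.total == sum(counts.values()) == 15
        assert counts["chromosome_selected"] == 10

    def test_no_addons_total_equals_selection(self):
        chrom_sel = [cand(i, 1_000 * i, score=0.9) for i in range(5)]
        assert assemble_manifest(chrom_sel).total == 5

    def test_duplicate_id_across_categories_rejected(self):
        c = cand(1, 100, score=0.9)
        with pytest.raises(ValueError):
            assemble_manifest([c], {"mito": [c]})

    def test_manifest_tsv_round_trips(self, tmp_path):
        manifest = assemble_manifest([cand(i, 1_000 * i, score=0.9) for i in range(4)])
        path = tmp_path / "panel.tsv"
        manifest.write_tsv(path)
        back = pd.read_csv(path, sep="\t")
        assert len(back) == 4 and list(back["id"]) == list(manifest.entries["id"])


class TestSpacingDistribution:
    def test_single_gap_counted(self):
        manifest = assemble_manifest([cand(0, 1_000, score=0.9), cand(1, 21_000, score=0.9)])
        hist = spacing_distribution(manifest, {"chr1": "macro"})
        assert hist["all"].sum() == 1
        assert hist.loc["[20000,22000)", "macro"] == 1

    def test_single_snp_contributes_no_gap(self):
        manifest = assemble_manifest([cand(0, 1_000, score=0.9)])
        hist = spacing_distribution(manifest, {"chr1": "macro"})
        assert "all" not in hist.columns or hist["all"].sum() == 0

    def test_total_gaps_identity(self):
        rng = np.random.default_rng(6)
        cands = []
        n_per_chrom = {}
        for chrom in ("chr1", "chr2"):
            pos = np.sort(rng.choice(100_000, size=20, replace=False))
            n_per_chrom[chrom] = len(pos)
            cands += [cand(f"{chrom}_{i}", int(p), chrom=chrom) for i, p in enumerate(pos)]
        manifest = assemble_manifest(cands)
        hist = spacing_distribution(manifest, {"chr1": "macro", "chr2": "micro"})
        assert hist["all"].sum() == sum(n - 1 for n in n_per_chrom.values())
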