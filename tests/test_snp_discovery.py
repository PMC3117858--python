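"""Augmented reference, unique mapping, pileup calling, MAF and merging."""

import numpy as np
import pytest

from rrlchip.rrl_design import ALU_I, SizeWindow, digest
from rrlchip.snp_discovery import (
    Pileup,
    SnpCall,
    build_augmented_reference,
    build_pileup,
    call_snps,
    consensus_quality,
    estimate_maf,
    map_reads,
    merge_populations,
    pooled_frequency_interval,
    read_sam,
    read_vcf_calls,
    write_population_vcf,
    write_sam,
)
from rrlchip.synthetic_data import generate_genome


class TestAugmentedReference:
    def test_short_contigs_excluded(self):
        ref = build_augmented_reference(
            {"chr1": "ACGT" * 10},
            {"c150": "A" * 150, "c250": "C" * 250},
            min_contig_bp=200,
        )
        assert set(ref.offset_table) == {"c250"}

    def test_empty_contig_set_gives_no_artificial_chromosome(self):
        ref = build_augmented_reference({"chr1": "ACGT"}, {}, min_contig_bp=200)
        assert ref.artificial_name is None
        assert set(ref.sequences) == {"chr1"}

    def test_coordinate_round_trip_for_every_kept_base(self):
        contigs = {"a": "ACGTACGT" * 30, "b": "GGCC" * 60, "c": "AT" * 150}
        ref = build_augmented_reference({}, contigs, min_contig_bp=200, spacer_len=10)
        for cid, (start, length) in ref.offset_table.items():
            for local in (0, 1, length - 1):
                art = ref.to_artificial(cid, local)
                assert ref.to_contig(art) == (cid, local)
                # sequence identity at the mapped coordinate
                assert ref.sequences[ref.artificial_name][art] == contigs[cid][local]

    def test_spacer_positions_map_to_none(self):
        ref = build_augmented_reference(
            {}, {"a": "A" * 200, "b": "C" * 200}, spacer_len=10
        )
        assert ref.to_contig(205) is None

    def test_duplicate_contig_collision_detected(self):
        with pytest.raises(ValueError):
            build_augmented_reference(
                {"chrArtificial": "ACGT"}, {"a": "A" * 200}, min_contig_bp=10
            )


@pytest.fixture(scope="module")
def reference():
    g = generate_genome({"macro": [30_000]}, seed=21)
    return g.as_dict()


class TestMapReads:
    def test_verbatim_read_maps_uniquely_to_origin(self, reference):
        chrom, seq = next(iter(reference.items()))
        read = seq[1000:1036]
        alns, counts = map_reads([("r1", read, "I" * 36)], reference)
        assert counts == {"unique": 1, "multi": 0, "unmapped": 0}
        assert alns[0].chrom == chrom and alns[0].pos == 1000
        assert alns[0].mapq == 37

    def test_duplicated_locus_is_multi_and_excluded(self, reference):
        chrom, seq = next(iter(reference.items()))
        dup = seq[1000:1036]
        ref2 = {chrom: seq + "TTTT" + dup + "TTTT"}
        alns, counts = map_reads([("r1", dup, "I" * 36)], ref2)
        assert counts["multi"] == 1 and not alns

    def test_one_mismatch_read_maps_with_lower_mapq(self, reference):
        chrom, seq = next(iter(reference.items()))
        read = list(seq[2000:2036])
        read[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[10]]
        alns, _ = map_reads([("r1", "".join(read), "I" * 36)], reference)
        assert alns and alns[0].pos == 2000 and alns[0].mapq == 25

    def test_reverse_strand_read_recovered(self, reference):
        from rrlchip.rrl_design import reverse_complement

        chrom, seq = next(iter(reference.items()))
        read = reverse_complement(seq[3000:3036])
        alns, _ = map_reads([("r1", read, "I" * 36)], reference)
        assert alns and alns[0].pos == 3000 and alns[0].strand == "-"

    def test_error_free_reads_from_unique_loci_map_back(self, reference):
        chrom, seq = next(iter(reference.items()))
        rng = np.random.default_rng(5)
        starts = rng.integers(0, len(seq) - 36, size=2_000)
        reads = [(f"r{i}:{s}", seq[s : s + 36], "I" * 36) for i, s in enumerate(starts)]
        alns, counts = map_reads(reads, reference)
        correct = sum(a.pos == int(a.qname.split(":")[1]) for a in alns)
        assert counts["unique"] >= 0.99 * len(reads)
        assert correct == counts["unique"]

    def test_read_longer_than_reference_is_unmapped(self):
        alns, counts = map_reads([("r1", "ACGT" * 20, "I" * 80)], {"c": "ACGTACGT"})
        assert counts["unmapped"] == 1 and not alns

    def test_sam_round_trip(self, reference, tmp_path):
        chrom, seq = next(iter(reference.items()))
        reads = [(f"r{i}", seq[p : p + 36], "I" * 36) for i, p in enumerate((50, 500))]
        alns, _ = map_reads(reads, reference)
        path = tmp_path / "aln.sam"
        write_sam(alns, reference, path)
        back = read_sam(path)
        assert [(a.qname, a.chrom, a.pos, a.mapq, a.sequence) for a in back] == [
            (a.qname, a.chrom, a.pos, a.mapq, a.sequence) for a in alns
        ]


def pileup_from_counts(ref, counts, qual=40, mapq=37):
    """Build a Pileup directly from {pos: {base: n}} for one chromosome."""
    chrom = "c"
    L = len(ref)
    p = Pileup(
        {chrom: np.zeros((4, L), dtype=np.int32)},
        {chrom: np.zeros((4, L), dtype=np.int64)},
        {chrom: np.zeros(L, dtype=np.int16)},
    )
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for pos, bases in counts.items():
        for base, n in bases.items():
            p.counts[chrom][idx[base], pos] += n
            p.qual_sums[chrom][idx[base], pos] += n * qual
        p.best_mapq[chrom][pos] = mapq
    return p


class TestCallSnps:
    REF = "ACGTACGTACGTACGTACGT"

    def _call(self, counts, mean_depth=20.0, **kw):
        pile = pileup_from_counts(self.REF, counts, **{k: v for k, v in kw.items() if k in ("qual", "mapq")})
        thresholds = {k: v for k, v in kw.items() if k not in ("qual", "mapq")}
        return call_snps(pile, {"c": self.REF}, "B1", mean_depth=mean_depth, **thresholds)

    def test_two_minor_reads_not_called(self):
        calls, rejects = self._call({4: {"A": 10, "G": 2}})
        assert calls == [] and rejects["minor_count"] == 1

    def test_three_minor_reads_called_with_maf(self):
        calls, _ = self._call({4: {"A": 9, "G": 3}})
        assert len(calls) == 1
        c = calls[0]
        assert (c.ref_allele, c.alt_allele) == ("A", "G")
        assert c.maf == pytest.approx(0.25)

    def test_depth_above_four_fold_mean_rejected(self):
        calls, rejects = self._call({4: {"A": 70, "G": 30}}, mean_depth=20.0)
        assert calls == [] and rejects["depth"] == 1

    def test_triallelic_site_rejected_and_counted(self):
        calls, rejects = self._call({4: {"A": 10, "G": 5, "C": 4}})
        assert calls == [] and rejects["triallelic"] == 1

    def test_low_mapq_site_rejected(self):
        calls, rejects = self._call({4: {"A": 9, "G": 3}}, mapq=5)
        assert calls == [] and rejects["mapq"] == 1

    def test_spacer_reference_base_never_called(self):
        ref = "ACGTNCGTACGTACGTACGT"
        pile = pileup_from_counts(ref, {4: {"A": 9, "G": 3}})
        calls, _ = call_snps(pile, {"c": ref}, "B1", mean_depth=20.0)
        assert calls == []


class TestEstimateMaf:
    @pytest.mark.parametrize("rc,ac,maf", [(5, 5, 0.5), (9, 3, 0.25), (12, 0, 0.0)])
    def test_count_ratio(self, rc, ac, maf):
        assert estimate_maf(rc, ac) == pytest.approx(maf)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            estimate_maf(0, 0)

    def test_never_exceeds_half(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            rc, ac = rng.integers(0, 100, 2)
            if rc + ac:
                assert estimate_maf(int(rc), int(ac)) <= 0.5


class TestConsensusQuality:
    def test_strong_biallelic_signal_is_capped(self):
        assert consensus_quality(9, 3, 40, 40) == 60.0

    def test_single_low_quality_alt_read_weak(self):
        assert consensus_quality(30, 1, 40, 8) < 10.0

    def test_no_alt_reads_zero(self):
        assert consensus_quality(10, 0, 40, 40) == 0.0


def _mk_call(pop, chrom="c", pos=5, ref="A", alt="G", rc=9, ac=3):
    return SnpCall(pop, chrom, pos, ref, alt, rc, ac, estimate_maf(rc, ac), 60.0, 37)


class TestMergePopulations:
    def test_site_shared_by_two_populations(self):
        merged, summary = merge_populations(
            {"B1": [_mk_call("B1")], "BL": [_mk_call("BL")]}
        )
        assert merged[0].n_populations_detected == 2
        assert summary["n_in_ge2_pops"] == 1

    def test_known_flag_lookup(self):
        merged, summary = merge_populations({"B1": [_mk_call("B1")]}, {("c", 5)})
        assert merged[0].known and summary["n_known"] == 1

    def test_conflicting_allele_pairs_flagged_and_excluded(self):
        merged, summary = merge_populations(
            {"B1": [_mk_call("B1", alt="G")], "BL": [_mk_call("BL", alt="T")]}
        )
        assert merged[0].allele_conflict
        assert summary["n_total"] == 0 and summary["n_conflict_excluded"] == 1

    def test_overall_maf_is_count_weighted(self):
        merged, _ = merge_populations(
            {"B1": [_mk_call("B1", rc=9, ac=3)], "BL": [_mk_call("BL", rc=5, ac=5)]}
        )
        assert merged[0].overall_maf == pytest.approx(8 / 22)

    def test_histogram_covers_all_clean_sites(self):
        calls = {"B1": [_mk_call("B1", pos=p, rc=9, ac=3 + p % 5) for p in range(10)]}
        _, summary = merge_populations(calls)
        assert sum(summary["maf_histogram"].values()) == summary["n_total"]


class TestVcfRoundTrip:
    def test_population_vcf_preserves_counts(self, tmp_path):
        ref = {"c": "ACGTACGTAC"}
        calls = [_mk_call("B1", pos=4, ref="A", alt="G", rc=11, ac=4)]
        path = tmp_path / "b1.vcf"
        write_population_vcf(calls, ref, path)
        back = read_vcf_calls(path, "B1")
        assert len(back) == 1
        b = back[0]
        assert (b.chrom, b.pos, b.ref_allele, b.alt_allele) == ("c", 4, "A", "G")
        assert (b.ref_count, b.alt_count) == (11, 4)
        assert b.maf == pytest.approx(4 / 15, abs=1e-6)


class TestPooledFrequencyInterval:
    def test_interval_widens_with_pool_resampling(self):
        lo1, hi1 = pooled_frequency_interval(0.3, 60, 10**9)  # ~pure binomial
        lo2, hi2 = pooled_frequency_interval(0.3, 60, 50)
        assert (hi2 - lo2) > (hi1 - lo1)

    def test_interval_contains_truth(self):
        lo, hi = pooled_frequency_interval(0.3, 60, 50)
        assert lo < 0.3 < hi


class TestEndToEndRecovery:
    def test_error_free_discovery_calls_only_truth_sites(
        self, small_genome, small_truth, small_discovery
    ):
        truth_pos = {(s.chrom, s.pos) for s in small_truth}
        assert small_discovery.merged  # something was discovered
        for m in small_discovery.merged:
            assert (m.chrom, m.pos) in truth_pos

    def test_estimated_mafs_near_planted_frequencies(
        self, small_truth, small_discovery
    ):
        truth = {(s.chrom, s.pos): s for s in small_truth}
        n_checked = n_inside = 0
        for m in small_discovery.merged:
            for pop, call in m.calls.items():
                f = truth[(m.chrom, m.pos)].pop_freq[pop]
                n = call.ref_count + call.alt_count
                lo, hi = pooled_frequency_interval(f, n, 50, conf=0.99)
                n_checked += 1
                n_inside += lo <= call.alt_count / n <= hi
        assert n_checked >= 10
        assert n_inside / n_checked >= 0.95
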