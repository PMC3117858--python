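"""Genotyping-array panel design: eligibility, priority, spacing, selection.

A candidate SNP enters the panel only if it is an Infinium type II assay
(allele pair A/C, A/G, T/C or T/G — one bead type), has a design score of
at least 0.6, and has no other known variant within 10 bp of the target
position (flanking variants disturb probe hybridisation).

Eligible candidates are ranked into 25 priority classes — a 5 x 5 lattice
of source/validation level by MAF tier — and a greedy scroll along each
chromosome picks the best candidate in a window around each target
position.  The spacing target depends on chromosome size class: avian
micro-chromosomes recombine at much higher rates per Mb than the
macro-chromosomes, so they receive denser coverage (20 kb on macros down
to 4 kb on micros, log-interpolated for the intermediate tiers).

Fixed add-on sets (SNPs on unplaced contigs, on chr_random bins, and on
the mitochondrion) bypass the spacing walk: they exist to cover sequence
the selection cannot reach.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "INFINIUM_II_PAIRS",
    "CandidateSnp",
    "classify_infinium",
    "flag_neighbors",
    "PriorityTable",
    "DEFAULT_PRIORITY_TABLE",
    "assign_priority",
    "eligible",
    "SpacingPlan",
    "spacing_plan",
    "select_panel",
    "PanelManifest",
    "assemble_manifest",
    "spacing_distribution",
]

#: The four allele pairs assayable with a single bead type.  A/T and C/G
#: need two bead types (type I) because both alleles extend with the same
#: channel otherwise.
INFINIUM_II_PAIRS = (
    frozenset("AC"),
    frozenset("AG"),
    frozenset("TC"),
    frozenset("TG"),
)

#: Candidate origin: a public SNP database only, the RRL discovery only,
#: both, or neither (legacy assay content predating the database release).
SOURCES = ("known_db", "rrl_novel", "rrl_and_db", "other")


def classify_infinium(alleles: Tuple[str, str]) -> str:
    """Infinium assay type from the unordered allele pair: 'II' or 'I'."""
    a, b = (x.upper() for x in alleles)
    if a == b:
        raise ValueError("alleles must differ")
    if not {a, b} <= set("ACGT"):
        raise ValueError(f"invalid allele pair {alleles!r}")
    return "II" if frozenset((a, b)) in INFINIUM_II_PAIRS else "I"


@dataclass(frozen=True)
class CandidateSnp:
    """A selectable marker with everything the priority rules look at."""

    id: str
    chrom: str
    pos: int
    alleles: Tuple[str, str]
    design_score: float
    validated: bool = False
    source: str = "rrl_novel"
    maf_broiler: Optional[float] = None
    maf_layer: Optional[float] = None
    neighbor_excluded: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.design_score <= 1.0:
            raise ValueError("design_score outside [0, 1]")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        for m in (self.maf_broiler, self.maf_layer):
            if m is not None and not 0.0 <= m <= 0.5:
                raise ValueError("MAF outside [0, 0.5]")

    @property
    def infinium_type(self) -> str:
        return classify_infinium(self.alleles)

    @property
    def mean_maf(self) -> float:
        vals = [m for m in (self.maf_broiler, self.maf_layer) if m is not None]
        return float(np.mean(vals)) if vals else float("nan")


def eligible(c: CandidateSnp, min_design_score: float = 0.6) -> bool:
    """Panel eligibility: type II, design score >= 0.6, no 10 bp neighbor."""
    return (
        c.infinium_type == "II"
        and c.design_score >= min_design_score
        and not c.neighbor_excluded
    )


def flag_neighbors(
    candidates: Sequence[CandidateSnp],
    all_known_variants: Mapping[str, Sequence[int]],
    window_bp: int = 10,
) -> List[CandidateSnp]:
    """Flag candidates with another variant within ±``window_bp`` bases.

    ``all_known_variants`` maps chromosome -> variant positions (the full
    variant catalogue, candidates included).  A candidate is excluded iff a
    *different* position on the same chromosome lies within the window.
    """
    sorted_pos = {c: np.sort(np.asarray(p)) for c, p in all_known_variants.items()}
    out = []
    for c in candidates:
        pos = sorted_pos.get(c.chrom)
        flagged = False
        if pos is not None and len(pos):
            lo = np.searchsorted(pos, c.pos - window_bp, side="left")
            hi = np.searchsorted(pos, c.pos + window_bp, side="right")
            n_in_window = hi - lo
            n_self = int(np.sum(pos[lo:hi] == c.pos))
            flagged = (n_in_window - n_self) > 0 or n_self > 1
        out.append(replace(c, neighbor_excluded=flagged))
    return out


# ---------------------------------------------------------------------------
# priority


@dataclass
class PriorityTable:
    """A 25-class priority lattice: source levels x MAF tiers, class 1 best.

    ``source_levels`` orders the five source/validation strata from most to
    least trusted; ``maf_tiers`` lists the lower bounds of the MAF tiers in
    descending order (a candidate falls in the first tier whose bound its
    tier MAF reaches; no MAF information lands in the last tier).  The
    class of a candidate is (source_level - 1) * n_tiers + tier.
    """

    maf_tier_bounds: Tuple[float, ...] = (0.4, 0.3, 0.2, 0.1)

    @property
    def n_classes(self) -> int:
        return 5 * (len(self.maf_tier_bounds) + 1)

    def source_level(self, c: CandidateSnp) -> int:
        has_b = c.maf_broiler is not None
        has_l = c.maf_layer is not None
        if c.validated and (has_b or has_l):
            return 1
        if c.source == "rrl_and_db":
            return 2
        if c.source == "rrl_novel" and has_b and has_l:
            return 3
        if c.source == "rrl_novel":
            return 4
        return 5  # database/legacy content without frequency information

    def maf_tier(self, c: CandidateSnp) -> int:
        vals = [m for m in (c.maf_broiler, c.maf_layer) if m is not None]
        if not vals:
            return len(self.maf_tier_bounds) + 1
        tier_maf = min(vals)  # a SNP is only as useful as its worst group
        for i, bound in enumerate(self.maf_tier_bounds, start=1):
            if tier_maf >= bound:
                return i
        return len(self.maf_tier_bounds) + 1

    def priority_class(self, c: CandidateSnp) -> int:
        n_tiers = len(self.maf_tier_bounds) + 1
        return (self.source_level(c) - 1) * n_tiers + self.maf_tier(c)


DEFAULT_PRIORITY_TABLE = PriorityTable()


def assign_priority(
    candidate: CandidateSnp, table: PriorityTable = DEFAULT_PRIORITY_TABLE
) -> int:
    """Priority class (1 = best) of an eligible candidate."""
    if not eligible(candidate):
        raise ValueError(f"candidate {candidate.id} is not panel-eligible")
    return table.priority_class(candidate)


# ---------------------------------------------------------------------------
# spacing


#: Size-class tier order used for log interpolation between the macro
#: spacing and the micro spacing (mirrors the four chromosome reporting
#: groups 1-5, 6-9, 10-14, 15-28 of a typical avian karyotype).
_CLASS_TIERS = {"macro": 0, "intermediate": 1.5, "micro": 3}


@dataclass
class SpacingPlan:
    target_spacing: Dict[str, int]  # chromosome -> bp

    def __getitem__(self, chrom: str) -> int:
        return self.target_spacing[chrom]


def spacing_plan(
    chromosome_classes: Mapping[str, str],
    macro_bp: int = 20_000,
    micro_bp: int = 4_000,
    chromosome_lengths: Optional[Mapping[str, int]] = None,
) -> SpacingPlan:
    """Target inter-SNP spacing per chromosome from its size class.

    Macro-chromosomes get ``macro_bp`` (default 20 kb), micro-chromosomes
    ``micro_bp`` (default 4 kb).  Intermediate chromosomes are placed on a
    log scale between the two; when lengths are supplied, the larger half
    of the intermediates takes the upper interpolation tier and the smaller
    half the lower, giving spacing monotone nonincreasing in chromosome
    size.  Only nuclear placed chromosomes belong in a plan.
    """
    if micro_bp > macro_bp:
        raise ValueError("micro spacing must not exceed macro spacing")
    inter = sorted(
        (c for c, cls in chromosome_classes.items() if cls == "intermediate"),
        key=lambda c: -(chromosome_lengths or {}).get(c, 0),
    )
    half = (len(inter) + 1) // 2
    ratio = micro_bp / macro_bp
    plan: Dict[str, int] = {}

    def interp(tier: float) -> int:
        return int(round(macro_bp * math.exp(math.log(ratio) * tier / 3.0)))

    for chrom, cls in chromosome_classes.items():
        if cls == "macro":
            plan[chrom] = macro_bp
        elif cls == "micro":
            plan[chrom] = micro_bp
        elif cls == "intermediate":
            tier = 1.0 if inter.index(chrom) < half else 2.0
            plan[chrom] = interp(tier)
        else:
            raise ValueError(f"{chrom}: size class {cls!r} has no spacing target")
    return SpacingPlan(plan)


# ---------------------------------------------------------------------------
# selection


def select_panel(
    candidates: Sequence[CandidateSnp],
    plan: SpacingPlan,
    table: PriorityTable = DEFAULT_PRIORITY_TABLE,
) -> Tuple[List[CandidateSnp], Dict[str, int]]:
    """Greedy scroll-along-chromosome selection.

    For each chromosome in the plan, maintain a cursor (last selected
    position, starting at 0) and repeatedly inspect the half-open window
    (cursor + spacing/2, cursor + 3*spacing/2]; select the candidate with
    the lowest priority-class number (ties: higher mean MAF, then closest
    to the target position cursor + spacing, then leftmost) and move the
    cursor there.  An empty window advances the cursor by one spacing and
    records a gap.  Deterministic for identical inputs.

    Only pre-filtered eligible candidates may be passed in.  Returns the
    selected candidates (chromosome order, then position) and a per-
    chromosome gap count.
    """
    for c in candidates:
        if not eligible(c):
            raise ValueError(f"ineligible candidate {c.id} passed to select_panel")
    by_chrom: Dict[str, List[CandidateSnp]] = {}
    for c in candidates:
        by_chrom.setdefault(c.chrom, []).append(c)
    selected: List[CandidateSnp] = []
    gaps: Dict[str, int] = {}
    for chrom in plan.target_spacing:
        spacing = plan[chrom]
        cands = sorted(by_chrom.get(chrom, []), key=lambda c: c.pos)
        gaps[chrom] = 0
        if not cands:
            continue
        positions = np.array([c.pos for c in cands])
        last_pos = positions[-1]
        cursor = 0
        while cursor + spacing // 2 < last_pos:
            lo = cursor + spacing // 2  # exclusive
            hi = cursor + spacing + spacing // 2  # inclusive
            i0 = int(np.searchsorted(positions, lo, side="right"))
            i1 = int(np.searchsorted(positions, hi, side="right"))
            window = cands[i0:i1]
            if not window:
                gaps[chrom] += 1
                cursor += spacing
                continue
            target = cursor + spacing
            best = min(
                window,
                key=lambda c: (
                    table.priority_class(c),
                    -(c.mean_maf if not math.isnan(c.mean_maf) else -1.0),
                    abs(c.pos - target),
                    c.pos,
                ),
            )
            selected.append(best)
            cursor = best.pos
    return selected, gaps


# ---------------------------------------------------------------------------
# manifest


CATEGORIES = ("chromosome_selected", "unplaced_contig", "chr_random", "mito")


@dataclass
class PanelManifest:
    """The final array content with per-SNP provenance category."""

    entries: pd.DataFrame  # id, chrom, pos, alleles, priority_class, category

    @property
    def total(self) -> int:
        return len(self.entries)

    def category_counts(self) -> Dict[str, int]:
        counts = self.entries["category"].value_counts().to_dict()
        return {cat: int(counts.get(cat, 0)) for cat in CATEGORIES}

    def source_counts(self) -> Dict[str, int]:
        counts = self.entries["source"].value_counts().to_dict()
        return {src: int(counts.get(src, 0)) for src in SOURCES}

    def write_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


def _entry_row(c: CandidateSnp, category: str, table: PriorityTable) -> Dict:
    return {
        "id": c.id,
        "chrom": c.chrom,
        "pos": c.pos,
        "alleles": "/".join(sorted(c.alleles)),
        "priority_class": table.priority_class(c),
        "category": category,
        "source": c.source,
        "validated": c.validated,
    }


def assemble_manifest(
    chromosome_selected: Sequence[CandidateSnp],
    addons: Mapping[str, Sequence[CandidateSnp]] = {},
    table: PriorityTable = DEFAULT_PRIORITY_TABLE,
) -> PanelManifest:
    """Combine the spaced selection with the fixed add-on sets.

    ``addons`` maps category ('unplaced_contig', 'chr_random', 'mito') to
    its SNPs; add-ons bypass spacing and eligibility.  Ids must be disjoint
    across categories.
    """
    rows: List[Dict] = [_entry_row(c, "chromosome_selected", table) for c in chromosome_selected]
    for category, snps in addons.items():
        if category not in CATEGORIES[1:]:
            raise ValueError(f"unknown add-on category {category!r}")
        rows.extend(_entry_row(c, category, table) for c in snps)
    df = pd.DataFrame(
        rows,
        columns=[
            "id", "chrom", "pos", "alleles", "priority_class",
            "category", "source", "validated",
        ],
    )
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate SNP ids across categories: {dupes[:5]}")
    return PanelManifest(df)


def spacing_distribution(
    manifest: PanelManifest,
    chromosome_classes: Mapping[str, str],
    bin_width_bp: int = 2_000,
    max_gap_bp: int = 60_000,
) -> pd.DataFrame:
    """Histogram of adjacent-SNP gaps per chromosome size class.

    Gaps are computed within chromosomes only, over the placed
    ('chromosome_selected') entries.  Bins are fixed-width (default 2 kb)
    up to ``max_gap_bp`` with a final overflow bin; rows are bins, columns
    size classes plus 'all'.
    """
    df = manifest.entries
    df = df[df["category"] == "chromosome_selected"]
    edges = list(range(0, max_gap_bp + bin_width_bp, bin_width_bp)) + [np.inf]
    labels = [
        f"[{edges[i]},{edges[i+1]})" if np.isfinite(edges[i + 1]) else f">={edges[i]}"
        for i in range(len(edges) - 1)
    ]
    gaps_by_class: Dict[str, List[int]] = {}
    for chrom, grp in df.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy())
        if len(pos) < 2:
            continue
        gaps = np.diff(pos)
        cls = chromosome_classes.get(chrom, "unknown")
        gaps_by_class.setdefault(cls, []).extend(int(g) for g in gaps)
        gaps_by_class.setdefault("all", []).extend(int(g) for g in gaps)
    out = pd.DataFrame(index=labels)
    for cls, gaps in sorted(gaps_by_class.items()):
        hist, _ = np.histogram(gaps, bins=edges)
        out[cls] = hist
    out.index.name = "gap_bin_bp"
    return out
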