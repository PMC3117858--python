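"""In-silico reduced-representation library (RRL) design.

A reduced representation library sequences a size-selected subset of
restriction fragments so that a small, reproducible fraction of the genome
is covered at high depth.  This module performs the in-silico part of that
design: complete digestion of a genome with a restriction enzyme, selection
of the fragments falling inside a gel-excision size window, and the basic
coverage/depth arithmetic (fold depth = sequenced bases landing on the
selection divided by selected bases).

All coordinates are 0-based, half-open.  Fragment inventories tile each
chromosome exactly: the first fragment starts at 0, the last ends at the
chromosome length, and adjacent fragments abut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import pandas as pd

__all__ = [
    "RestrictionEnzyme",
    "ALU_I",
    "FragmentInventory",
    "SizeWindow",
    "digest",
    "select_fraction",
    "expected_depth",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme with a fixed recognition site and cut offset.

    ``cut_offset`` is the position of the cut within the recognition site
    (0 .. len(site)).  AluI recognises AGCT and cuts bluntly between the G
    and the C (AG^CT), i.e. offset 2.
    """

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition_site.upper()
        if not site:
            raise ValueError("recognition site must be non-empty")
        if not set(site) <= set("ACGT"):
            raise ValueError(f"invalid recognition site {site!r}")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError("cut_offset must lie within the recognition site")
        object.__setattr__(self, "recognition_site", site)

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition_site) == self.recognition_site


#: AluI: blunt cutter, AG^CT.  The site is its own reverse complement, so
#: scanning the forward strand finds every cut.
ALU_I = RestrictionEnzyme("AluI", "AGCT", 2)


@dataclass
class FragmentInventory:
    """Per-chromosome sorted, abutting restriction fragments."""

    fragments: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)
    chrom_lengths: Dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        for chrom, frags in self.fragments.items():
            length = self.chrom_lengths[chrom]
            if not frags:
                raise ValueError(f"{chrom}: empty fragment list")
            if frags[0][0] != 0 or frags[-1][1] != length:
                raise ValueError(f"{chrom}: fragments do not tile the chromosome")
            for (s0, e0), (s1, e1) in zip(frags, frags[1:]):
                if e0 != s1:
                    raise ValueError(f"{chrom}: fragments not abutting at {e0}/{s1}")
            if any(e <= s for s, e in frags):
                raise ValueError(f"{chrom}: zero-length fragment")

    def lengths(self) -> List[int]:
        return [e - s for frags in self.fragments.values() for s, e in frags]

    def length_histogram(self) -> pd.Series:
        """Counts of fragments by exact length (index = length in bp)."""
        return pd.Series(self.lengths()).value_counts().sort_index()

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def to_bed(self) -> pd.DataFrame:
        rows = [
            (chrom, s, e)
            for chrom, frags in self.fragments.items()
            for s, e in frags
        ]
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def write_bed(self, path) -> None:
        self.to_bed().to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read_bed(cls, path, chrom_lengths: Mapping[str, int]) -> "FragmentInventory":
        bed = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"])
        frags: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, grp in bed.groupby("chrom", sort=False):
            frags[str(chrom)] = sorted(
                (int(s), int(e)) for s, e in zip(grp["start"], grp["end"])
            )
        inv = cls(frags, dict(chrom_lengths))
        inv.validate()
        return inv

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FragmentInventory):
            return NotImplemented
        return (
            self.fragments == other.fragments
            and self.chrom_lengths == other.chrom_lengths
        )


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive fragment-length selection window (gel excision range)."""

    min_bp: int
    max_bp: int

    def __post_init__(self) -> None:
        if not 0 < self.min_bp <= self.max_bp:
            raise ValueError("require 0 < min_bp <= max_bp")

    def contains(self, length: int) -> bool:
        return self.min_bp <= length <= self.max_bp


def _cut_positions(seq: str, enzyme: RestrictionEnzyme) -> List[int]:
    """All cut coordinates on one sequence, scanning left to right.

    Every exact occurrence of the recognition site cuts at
    site_start + cut_offset.  For a non-palindromic enzyme the reverse
    strand is scanned too (cut mapped back to forward coordinates).
    """
    site = enzyme.recognition_site
    cuts = set()
    start = seq.find(site)
    while start != -1:
        cuts.add(start + enzyme.cut_offset)
        start = seq.find(site, start + 1)
    if not enzyme.is_palindromic:
        rc_site = reverse_complement(site)
        start = seq.find(rc_site)
        while start != -1:
            # cut_offset measured from the site 5' end on the minus strand
            cuts.add(start + len(site) - enzyme.cut_offset)
            start = seq.find(rc_site, start + 1)
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(genome, enzyme: RestrictionEnzyme = ALU_I) -> FragmentInventory:
    """Complete digest of a genome: fragments between consecutive cut sites.

    ``genome`` is anything with ``.chromosomes`` yielding (name, sequence)
    pairs (a :class:`~rrlchip.synthetic_data.SyntheticGenome`), or a mapping
    name -> sequence.
    """
    if hasattr(genome, "chromosomes"):
        items = [(c.name, c.sequence) for c in genome.chromosomes]
    else:
        items = list(genome.items())
    if not items:
        raise ValueError("genome is empty")
    inv = FragmentInventory()
    for name, seq in items:
        seq = seq.upper()
        cuts = _cut_positions(seq, enzyme)
        bounds = [0] + cuts + [len(seq)]
        inv.fragments[name] = list(zip(bounds[:-1], bounds[1:]))
        inv.chrom_lengths[name] = len(seq)
    inv.validate()
    return inv


def select_fraction(
    inventory: FragmentInventory, window: SizeWindow
) -> Tuple[pd.DataFrame, int, float]:
    """Keep fragments whose length falls inside the (inclusive) window.

    Returns (selected fragments as a BED-style DataFrame, selected bp,
    fraction of the genome selected).
    """
    rows = [
        (chrom, s, e)
        for chrom, frags in inventory.fragments.items()
        for s, e in frags
        if window.contains(e - s)
    ]
    bed = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    selected_bp = int((bed["end"] - bed["start"]).sum()) if len(bed) else 0
    fraction = selected_bp / inventory.total_bp if inventory.total_bp else 0.0
    return bed, selected_bp, fraction


def expected_depth(selected_bp: int, total_sequenced_bp: int) -> float:
    """Fold sequence depth over the selected fraction.

    depth = sequenced bases landing on the selection / selected bases.
    """
    if selected_bp <= 0:
        raise ValueError("selected_bp must be positive")
    return total_sequenced_bp / selected_bp
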