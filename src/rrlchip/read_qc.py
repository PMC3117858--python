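"""Read filters for RRL short-read data, with per-filter accounting.

Four filters are implemented, mirroring a pooled RRL quality pipeline:

1. mean base quality — drop a read whose arithmetic mean Phred score is
   below 12;
2. restriction-motif start — drop a read whose first two bases are not
   "CT" (on blunt AG^CT fragments every genuine fragment end begins CT);
3. homopolymer — drop a read containing a single-base run longer than 17
   (>= half a 36 bp read), a proxy for low-complexity/repeat sequence;
4. over-represented alignment start sites — after alignment, drop every
   read whose (chrom, start, strand) start site carries more reads than
   5x the estimated average sequence depth, a proxy for collapsed repeats.

The per-read filters are pure functions; ``run_read_filters`` applies them
in a fixed order (quality, motif, homopolymer) and attributes each dropped
read to the first filter that failed, so that counts conserve:
input = retained + sum(removed per filter).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ReadRecord",
    "QcReport",
    "filter_mean_quality",
    "filter_start_motif",
    "filter_homopolymer",
    "filter_overrepresented_sites",
    "run_read_filters",
]


@dataclass(frozen=True)
class ReadRecord:
    id: str
    mate: int
    sequence: str
    qualities: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError("sequence and qualities lengths differ")
        if self.mate not in (1, 2):
            raise ValueError("mate must be 1 or 2")

    @classmethod
    def from_fastq_tuple(cls, rid: str, seq: str, qual: str) -> "ReadRecord":
        mate = 2 if rid.endswith("/2") else 1
        return cls(rid, mate, seq.upper(), tuple(ord(c) - 33 for c in qual))


@dataclass
class QcReport:
    input_count: int = 0
    removed_by: Dict[str, int] = field(default_factory=dict)
    retained_count: int = 0

    def validate(self) -> None:
        if self.input_count != self.retained_count + sum(self.removed_by.values()):
            raise ValueError("QC counts do not conserve")

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_count": self.input_count,
                "removed_by": self.removed_by,
                "retained_count": self.retained_count,
            },
            indent=2,
        )

    def __str__(self) -> str:
        lines = [f"reads in: {self.input_count}"]
        for name, n in self.removed_by.items():
            lines.append(f"  removed by {name}: {n}")
        lines.append(f"reads retained: {self.retained_count}")
        return "\n".join(lines)


def filter_mean_quality(read: ReadRecord, min_mean: float = 12.0) -> bool:
    """Keep iff the arithmetic mean Phred quality is >= ``min_mean``."""
    if not read.qualities:
        raise ValueError("read has no quality values")
    return float(np.mean(read.qualities)) >= min_mean


def filter_start_motif(read: ReadRecord, motif: str = "CT") -> bool:
    """Keep iff the read starts with the post-cut restriction motif.

    N bases never match the motif.
    """
    return read.sequence[: len(motif)].upper() == motif.upper()


def longest_homopolymer(seq: str) -> int:
    best = run = 0
    prev = None
    for b in seq:
        if b == prev and b != "N":  # N breaks a run
            run += 1
        else:
            run = 1 if b != "N" else 0
            prev = b
        best = max(best, run)
    return best


def filter_homopolymer(read: ReadRecord, max_run: Optional[int] = None) -> bool:
    """Keep iff the longest single-base run is <= ``max_run``.

    The default threshold is floor(L/2) - 1 + 1 = 17 for 36 bp reads: runs
    strictly longer than 17 bases (i.e. >= half the read) are dropped.
    """
    if max_run is None:
        max_run = max(len(read.sequence) // 2 - 1, 1)
        if len(read.sequence) == 36:
            max_run = 17
    return longest_homopolymer(read.sequence) <= max_run


_PER_READ_FILTERS = (
    ("mean_quality", filter_mean_quality),
    ("start_motif", filter_start_motif),
    ("homopolymer", filter_homopolymer),
)


def run_read_filters(
    reads: Iterable[ReadRecord],
    min_mean: float = 12.0,
    motif: str = "CT",
    max_run: Optional[int] = None,
    apply_motif_to_mate2: bool = True,
) -> Tuple[List[ReadRecord], QcReport]:
    """Apply the three per-read filters with first-failing attribution.

    On blunt-cutter fragments both mates start at a cut, so the motif filter
    applies to both by default; ``apply_motif_to_mate2=False`` restricts it
    to first-in-pair reads.
    """
    report = QcReport(removed_by={name: 0 for name, _ in _PER_READ_FILTERS})
    kept: List[ReadRecord] = []
    for read in reads:
        report.input_count += 1
        verdicts = {
            "mean_quality": filter_mean_quality(read, min_mean),
            "start_motif": (
                filter_start_motif(read, motif)
                if (read.mate == 1 or apply_motif_to_mate2)
                else True
            ),
            "homopolymer": filter_homopolymer(read, max_run),
        }
        for name, _ in _PER_READ_FILTERS:
            if not verdicts[name]:
                report.removed_by[name] += 1
                break
        else:
            kept.append(read)
            report.retained_count += 1
    report.validate()
    return kept, report


def filter_overrepresented_sites(
    alignments: Sequence[Tuple[str, int, str]],
    mean_depth: float,
    factor: float = 5.0,
) -> Tuple[List[int], int]:
    """Drop all reads stacking at over-represented alignment start sites.

    A "site" is the (chrom, start, strand) alignment start key — RRL reads
    stack at restriction cut sites, so start multiplicity is the natural
    unit.  Every read at a site observed strictly more than
    ``factor x mean_depth`` times is removed.

    Returns (indices of kept alignments, number removed).
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    counts: Dict[Tuple[str, int, str], int] = {}
    for chrom, start, strand in alignments:
        counts[(chrom, start, strand)] = counts.get((chrom, start, strand), 0) + 1
    cutoff = factor * mean_depth
    kept = [
        i
        for i, key in enumerate(alignments)
        if counts[(key[0], key[1], key[2])] <= cutoff
    ]
    return kept, len(alignments) - len(kept)
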