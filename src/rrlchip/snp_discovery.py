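"""Pooled SNP discovery from uniquely mapped short reads.

The discovery model: each population is sequenced as a pooled RRL library;
reads are aligned to the reference (optionally augmented with an artificial
chromosome concatenating novel contigs), only reads mapping to a single
unique location are piled up, and a site is called a SNP when

* exactly two alleles are observed, one of them the reference base,
* the minor allele is supported by at least ``min_minor_reads`` reads
  (default 3),
* site depth does not exceed ``max_depth_factor`` x the average depth
  (default 4x; guards against collapsed paralogues),
* the best mapping quality at the site and the consensus quality both
  reach 10.

The minor allele frequency of a call is estimated by direct read counting:
maf = min(ref_count, alt_count) / (ref_count + alt_count), so maf <= 0.5 by
construction.  Per-population calls are then merged across populations,
cross-referenced against a known-SNP table, and summarised (sites shared by
>= 2 populations, count-weighted mean MAF, MAF spectrum histogram).

The built-in mapper is a seed-and-extend unique mapper sufficient for
short synthetic reads: exact non-overlapping seeds, at most two mismatches
(the usual short-read aligner default for 36-mers), and a three-way
verdict (unique / multi / unmapped).  Map quality is 37 / 25 / 15 for a
unique 0-/1-/2-mismatch hit; ties get 0 and are excluded.  Alignments can
also be ingested from SAM, in which case the file's own MAPQ values are
used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .rrl_design import reverse_complement

__all__ = [
    "AugmentedReference",
    "build_augmented_reference",
    "Alignment",
    "map_reads",
    "write_sam",
    "read_sam",
    "Pileup",
    "build_pileup",
    "SnpCall",
    "call_snps",
    "estimate_maf",
    "MergedSnp",
    "merge_populations",
    "calls_to_frame",
    "merged_to_frame",
    "write_population_vcf",
    "write_merged_vcf",
    "read_vcf_calls",
    "MAF_BINS",
]

#: map quality by mismatch count for a unique best hit; ties get 0
MAPQ_BY_MISMATCH = {0: 37, 1: 25, 2: 15}
MAPQ_UNIQUE_EXACT = 37
MAPQ_UNIQUE_ONE_MM = 25

#: MAF spectrum bin edges: [0,0.05), [0.05,0.10), ..., [0.45,0.50]
MAF_BINS = [round(0.05 * i, 2) for i in range(11)]


# ---------------------------------------------------------------------------
# augmented reference


@dataclass
class AugmentedReference:
    """Assembly chromosomes plus an artificial chromosome of novel contigs.

    Contigs at least ``min_contig_bp`` long are concatenated, separated by
    runs of N (``spacer_len`` bases), into one artificial chromosome.  The
    offset table maps each kept contig to its (start, length) on the
    artificial chromosome, and coordinates round-trip exactly; positions
    inside spacers map to no contig.
    """

    sequences: Dict[str, str]
    artificial_name: Optional[str]
    offset_table: Dict[str, Tuple[int, int]]

    def to_artificial(self, contig_id: str, local_pos: int) -> int:
        start, length = self.offset_table[contig_id]
        if not 0 <= local_pos < length:
            raise IndexError("position outside contig")
        return start + local_pos

    def to_contig(self, artificial_pos: int) -> Optional[Tuple[str, int]]:
        for cid, (start, length) in self.offset_table.items():
            if start <= artificial_pos < start + length:
                return cid, artificial_pos - start
        return None


def build_augmented_reference(
    assembly: Mapping[str, str],
    contigs: Mapping[str, str],
    min_contig_bp: int = 200,
    spacer_len: int = 50,
    artificial_name: str = "chrArtificial",
) -> AugmentedReference:
    """Append novel contigs >= ``min_contig_bp`` as one artificial chromosome."""
    if len(set(contigs)) != len(list(contigs)):
        raise ValueError("duplicate contig id")
    kept = [(cid, seq) for cid, seq in contigs.items() if len(seq) >= min_contig_bp]
    sequences = {name: seq.upper() for name, seq in assembly.items()}
    if not kept:
        return AugmentedReference(sequences, None, {})
    parts: List[str] = []
    offsets: Dict[str, Tuple[int, int]] = {}
    cursor = 0
    spacer = "N" * spacer_len
    for i, (cid, seq) in enumerate(kept):
        if i > 0:
            parts.append(spacer)
            cursor += spacer_len
        offsets[cid] = (cursor, len(seq))
        parts.append(seq.upper())
        cursor += len(seq)
    if artificial_name in sequences:
        raise ValueError(f"artificial chromosome name {artificial_name!r} collides")
    sequences[artificial_name] = "".join(parts)
    return AugmentedReference(sequences, artificial_name, offsets)


# ---------------------------------------------------------------------------
# mapping


@dataclass(frozen=True)
class Alignment:
    qname: str
    chrom: str
    pos: int  # 0-based leftmost
    strand: str  # '+' or '-'
    mapq: int
    sequence: str  # on the reference (forward) strand
    qualities: Tuple[int, ...]  # reference-strand order
    n_mismatch: int


class _ReferenceIndex:
    """Exact-match seed k-mer index over all reference chromosomes."""

    def __init__(self, sequences: Mapping[str, str], seed_len: int):
        self.sequences = dict(sequences)
        self.seed_len = seed_len
        self.index: Dict[str, List[Tuple[str, int]]] = {}
        for chrom, seq in self.sequences.items():
            for i in range(0, len(seq) - seed_len + 1):
                kmer = seq[i : i + seed_len]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((chrom, i))


def _mismatches(ref: str, query: str, cap: int) -> int:
    mm = 0
    for a, b in zip(ref, query):
        if a != b:
            mm += 1
            if mm > cap:
                return mm
    return mm


def map_reads(
    reads: Sequence[Tuple[str, str, str]],
    reference: Mapping[str, str],
    max_mismatch: int = 2,
    seed_len: Optional[int] = None,
) -> Tuple[List[Alignment], Dict[str, int]]:
    """Map reads to a reference, reporting only unique best hits.

    Each read is placed by exact non-overlapping seeds (read_len /
    (max_mismatch + 1) bases each, so at least one seed is clean by
    pigeonhole) and verified allowing at most ``max_mismatch``
    substitutions on either strand.  A read is
    ``unique`` when a single location attains the best mismatch count,
    ``multi`` when two or more tie (excluded), else ``unmapped``.

    Returns (alignments of unique reads, verdict counts).
    """
    if not reads:
        return [], {"unique": 0, "multi": 0, "unmapped": 0}
    read_len = len(reads[0][1])
    if seed_len is None:
        seed_len = max(read_len // (max_mismatch + 1), 10)
    idx = _ReferenceIndex(reference, seed_len)
    counts = {"unique": 0, "multi": 0, "unmapped": 0}
    alignments: List[Alignment] = []
    for rid, seq, qual in reads:
        seq = seq.upper()
        hits: Dict[Tuple[str, int, str], int] = {}
        for strand in "+-":
            query = seq if strand == "+" else reverse_complement(seq)
            offsets = range(0, len(query) - seed_len + 1, seed_len)
            candidates: Set[Tuple[str, int]] = set()
            for off in offsets:
                for chrom, spos in idx.index.get(query[off : off + seed_len], ()):
                    start = spos - off
                    if 0 <= start <= len(idx.sequences[chrom]) - len(query):
                        candidates.add((chrom, start))
            for chrom, start in candidates:
                ref = idx.sequences[chrom][start : start + len(query)]
                mm = _mismatches(ref, query, max_mismatch)
                if mm <= max_mismatch:
                    hits[(chrom, start, strand)] = mm
        if not hits:
            counts["unmapped"] += 1
            continue
        best = min(hits.values())
        best_hits = [k for k, mm in hits.items() if mm == best]
        if len(best_hits) > 1:
            counts["multi"] += 1
            continue
        chrom, start, strand = best_hits[0]
        counts["unique"] += 1
        mapq = MAPQ_BY_MISMATCH.get(best, 15)
        quals = tuple(ord(c) - 33 for c in qual)
        if strand == "-":
            fwd_seq = reverse_complement(seq)
            fwd_qual = quals[::-1]
        else:
            fwd_seq, fwd_qual = seq, quals
        alignments.append(
            Alignment(rid, chrom, start, strand, mapq, fwd_seq, fwd_qual, best)
        )
    return alignments, counts


def write_sam(alignments: Iterable[Alignment], reference: Mapping[str, str], path) -> None:
    """Emit ungapped alignments as plain-text SAM (via pysam)."""
    import pysam

    names = list(reference)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(reference[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            a = pysam.AlignedSegment(out.header)
            a.query_name = aln.qname
            a.query_sequence = aln.sequence
            a.query_qualities = list(aln.qualities)
            a.reference_id = tid[aln.chrom]
            a.reference_start = aln.pos
            a.mapping_quality = aln.mapq
            a.cigarstring = f"{len(aln.sequence)}M"
            a.flag = 16 if aln.strand == "-" else 0
            a.set_tag("NM", aln.n_mismatch)
            out.write(a)


def read_sam(path) -> List[Alignment]:
    """Ingest ungapped single-end alignments from SAM, keeping mapped reads
    and the file's own MAPQ values."""
    import pysam

    alignments: List[Alignment] = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            quals = tuple(a.query_qualities) if a.query_qualities is not None else ()
            alignments.append(
                Alignment(
                    a.query_name,
                    a.reference_name,
                    a.reference_start,
                    "-" if a.is_reverse else "+",
                    a.mapping_quality,
                    a.query_sequence.upper(),
                    quals,
                    int(a.get_tag("NM")) if a.has_tag("NM") else 0,
                )
            )
    return alignments


# ---------------------------------------------------------------------------
# pileup


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}
_IDX_BASE = "ACGT"


@dataclass
class Pileup:
    """Per-chromosome base counts from uniquely mapped reads.

    ``counts[chrom]`` is a 4 x L array of reads per allele; ``qual_sums``
    accumulates base qualities per allele for consensus-quality evaluation;
    ``best_mapq`` the maximum map quality of any read covering a position.
    Only reads with mapq >= ``min_mapq`` contribute.
    """

    counts: Dict[str, np.ndarray]
    qual_sums: Dict[str, np.ndarray]
    best_mapq: Dict[str, np.ndarray]

    def depth(self, chrom: str) -> np.ndarray:
        return self.counts[chrom].sum(axis=0)

    def mean_depth(self) -> float:
        """Average sequence depth: aligned bases / positions covered >= 1x."""
        total = 0
        covered = 0
        for chrom in self.counts:
            d = self.depth(chrom)
            total += int(d.sum())
            covered += int((d > 0).sum())
        if covered == 0:
            raise ValueError("pileup is empty")
        return total / covered


def build_pileup(
    alignments: Iterable[Alignment],
    reference: Mapping[str, str],
    min_mapq: int = 10,
) -> Pileup:
    counts = {c: np.zeros((4, len(s)), dtype=np.int32) for c, s in reference.items()}
    qual_sums = {c: np.zeros((4, len(s)), dtype=np.int64) for c, s in reference.items()}
    best_mapq = {c: np.zeros(len(s), dtype=np.int16) for c, s in reference.items()}
    for aln in alignments:
        if aln.mapq < min_mapq:
            continue
        cc, qq, bm = counts[aln.chrom], qual_sums[aln.chrom], best_mapq[aln.chrom]
        for i, base in enumerate(aln.sequence):
            bi = _BASE_IDX.get(base)
            if bi is None:
                continue
            pos = aln.pos + i
            cc[bi, pos] += 1
            if aln.qualities:
                qq[bi, pos] += aln.qualities[i]
            bm[pos] = max(bm[pos], aln.mapq)
    return Pileup(counts, qual_sums, best_mapq)


# ---------------------------------------------------------------------------
# calling


@dataclass(frozen=True)
class SnpCall:
    population_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ref_count: int
    alt_count: int
    maf: float
    consensus_quality: float
    best_mapq: int


def estimate_maf(ref_count: int, alt_count: int) -> float:
    """MAF by direct read counting: min(counts) / total, hence <= 0.5."""
    total = ref_count + alt_count
    if total == 0:
        raise ValueError("no reads at site")
    return min(ref_count, alt_count) / total


def consensus_quality(
    ref_count: int,
    alt_count: int,
    mean_ref_qual: float,
    mean_alt_qual: float,
    cap: float = 60.0,
) -> float:
    """Phred-scaled posterior odds that a site is biallelic vs. ref-only.

    Under independent sequencing errors with per-allele mean error
    probability e = 10^(-Q/10), the likelihood of the observed counts is
    compared between a biallelic model (allele mixture at the observed
    proportions) and a monoallelic-reference model; the log10 ratio times
    ten, floored at 0 and capped at ``cap``, is the consensus quality.
    """
    depth = ref_count + alt_count
    if depth == 0 or alt_count == 0:
        return 0.0
    f_alt = alt_count / depth
    f_ref = 1.0 - f_alt
    e_ref = 10 ** (-mean_ref_qual / 10.0)
    e_alt = 10 ** (-mean_alt_qual / 10.0)
    # biallelic: each read drawn from the allele mixture with its own error
    l1 = ref_count * math.log10(f_ref * (1 - e_ref) + f_alt * e_ref / 3) + (
        alt_count * math.log10(f_alt * (1 - e_alt) + f_ref * e_alt / 3)
    )
    # monoallelic ref: alt reads are all errors
    l0 = ref_count * math.log10(1 - e_ref) + alt_count * math.log10(e_alt / 3)
    return float(min(cap, max(0.0, 10.0 * (l1 - l0))))


def call_snps(
    pileup: Pileup,
    reference: Mapping[str, str],
    population_id: str,
    mean_depth: Optional[float] = None,
    min_consensus: float = 10.0,
    min_best_mapq: int = 10,
    min_minor_reads: int = 3,
    max_depth_factor: float = 4.0,
) -> Tuple[List[SnpCall], Dict[str, int]]:
    """Call biallelic SNPs from a pileup under count and quality thresholds.

    Sites rejected after the base screens are tallied in the second return
    value: ``triallelic`` (more than two alleles), ``non_ref_pair`` (two
    alleles but neither is the reference base), ``minor_count``, ``depth``,
    ``consensus``, ``mapq``.  Reference positions that are N (e.g. spacer
    runs in an artificial chromosome) are never called.
    """
    if mean_depth is None:
        mean_depth = pileup.mean_depth()
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    max_depth = max_depth_factor * mean_depth
    calls: List[SnpCall] = []
    rejects = {
        "triallelic": 0,
        "non_ref_pair": 0,
        "minor_count": 0,
        "depth": 0,
        "consensus": 0,
        "mapq": 0,
    }
    for chrom, cc in pileup.counts.items():
        refseq = reference[chrom]
        depth = cc.sum(axis=0)
        multi = np.nonzero((cc > 0).sum(axis=0) >= 2)[0]
        for pos in multi:
            ref_base = refseq[pos]
            if ref_base not in _BASE_IDX:
                continue  # N / spacer
            observed = [b for b in range(4) if cc[b, pos] > 0]
            if len(observed) > 2:
                rejects["triallelic"] += 1
                continue
            ref_i = _BASE_IDX[ref_base]
            if ref_i not in observed:
                rejects["non_ref_pair"] += 1
                continue
            alt_i = observed[0] if observed[1] == ref_i else observed[1]
            ref_count = int(cc[ref_i, pos])
            alt_count = int(cc[alt_i, pos])
            if min(ref_count, alt_count) < min_minor_reads:
                rejects["minor_count"] += 1
                continue
            if depth[pos] > max_depth:
                rejects["depth"] += 1
                continue
            bm = int(pileup.best_mapq[chrom][pos])
            if bm < min_best_mapq:
                rejects["mapq"] += 1
                continue
            qs = pileup.qual_sums[chrom]
            mean_rq = qs[ref_i, pos] / ref_count if ref_count else 30.0
            mean_aq = qs[alt_i, pos] / alt_count if alt_count else 30.0
            cq = consensus_quality(ref_count, alt_count, mean_rq, mean_aq)
            if cq < min_consensus:
                rejects["consensus"] += 1
                continue
            calls.append(
                SnpCall(
                    population_id,
                    chrom,
                    int(pos),
                    ref_base,
                    _IDX_BASE[alt_i],
                    ref_count,
                    alt_count,
                    estimate_maf(ref_count, alt_count),
                    cq,
                    bm,
                )
            )
    return calls, rejects


# ---------------------------------------------------------------------------
# merging


@dataclass
class MergedSnp:
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    calls: Dict[str, SnpCall]
    known: bool
    allele_conflict: bool

    @property
    def n_populations_detected(self) -> int:
        return len(self.calls)

    @property
    def overall_maf(self) -> float:
        """Count-weighted MAF over the detecting populations."""
        ref = sum(c.ref_count for c in self.calls.values())
        alt = sum(c.alt_count for c in self.calls.values())
        return estimate_maf(ref, alt)


def merge_populations(
    calls_by_pop: Mapping[str, Sequence[SnpCall]],
    known_table: Optional[Set[Tuple[str, int]]] = None,
) -> Tuple[List[MergedSnp], Dict[str, object]]:
    """Combine per-population calls into one merged SNP per site.

    Sites where populations disagree on the allele pair are flagged as
    conflicts and excluded from the summary statistics.  The summary
    reports the total, the count detected in >= 2 populations, the count
    present in the known table, the count-weighted mean MAF, and the MAF
    spectrum histogram on [0, 0.05), ..., [0.45, 0.50] bins.
    """
    known_table = known_table or set()
    sites: Dict[Tuple[str, int], Dict[str, SnpCall]] = {}
    for pop, calls in calls_by_pop.items():
        for c in calls:
            sites.setdefault((c.chrom, c.pos), {})[pop] = c
    merged: List[MergedSnp] = []
    for (chrom, pos), by_pop in sorted(sites.items()):
        pairs = {frozenset((c.ref_allele, c.alt_allele)) for c in by_pop.values()}
        conflict = len(pairs) > 1
        first = next(iter(by_pop.values()))
        merged.append(
            MergedSnp(
                chrom,
                pos,
                first.ref_allele,
                first.alt_allele,
                dict(by_pop),
                (chrom, pos) in known_table,
                conflict,
            )
        )
    clean = [m for m in merged if not m.allele_conflict]
    mafs = np.array([m.overall_maf for m in clean]) if clean else np.array([])
    hist, _ = np.histogram(mafs, bins=MAF_BINS) if len(mafs) else (np.zeros(10, int), None)
    summary = {
        "n_total": len(clean),
        "n_conflict_excluded": len(merged) - len(clean),
        "n_in_ge2_pops": sum(m.n_populations_detected >= 2 for m in clean),
        "n_known": sum(m.known for m in clean),
        "mean_maf": float(mafs.mean()) if len(mafs) else float("nan"),
        "maf_histogram": {
            f"[{MAF_BINS[i]:.2f},{MAF_BINS[i+1]:.2f})": int(h)
            for i, h in enumerate(hist)
        },
    }
    return merged, summary


def pooled_frequency_interval(
    freq: float, n_reads: int, n_haplotypes: int, conf: float = 0.99
) -> Tuple[float, float]:
    """Confidence interval for the read-level alt fraction in a pooled library.

    Reads draw template haplotypes i.i.d. (with replacement) from the 2N
    founder haplotypes of the pool, so the variance of the observed alt
    read fraction around the population frequency f is

        f (1 - f) [ 1/n + (1 - 1/n) / H ]

    with n reads and H haplotypes — the binomial read-sampling term plus
    the haplotype-resampling term.  Returns the normal-approximation
    central interval at confidence ``conf``.
    """
    from scipy.stats import norm

    if n_reads <= 0 or n_haplotypes <= 0:
        raise ValueError("n_reads and n_haplotypes must be positive")
    z = norm.ppf(0.5 + conf / 2.0)
    var = freq * (1 - freq) * (1 / n_reads + (1 - 1 / n_reads) / n_haplotypes)
    half = z * math.sqrt(var)
    return freq - half, freq + half


def calls_to_frame(calls: Sequence[SnpCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "population_id": c.population_id,
                "chrom": c.chrom,
                "pos": c.pos,
                "ref": c.ref_allele,
                "alt": c.alt_allele,
                "ref_count": c.ref_count,
                "alt_count": c.alt_count,
                "maf": c.maf,
                "consensus_quality": c.consensus_quality,
                "best_mapq": c.best_mapq,
            }
            for c in calls
        ]
    )


def merged_to_frame(merged: Sequence[MergedSnp]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": m.chrom,
                "pos": m.pos,
                "ref": m.ref_allele,
                "alt": m.alt_allele,
                "n_populations": m.n_populations_detected,
                "known": m.known,
                "allele_conflict": m.allele_conflict,
                "overall_maf": m.overall_maf,
            }
            for m in merged
        ]
    )


# ---------------------------------------------------------------------------
# VCF I/O (pysam-backed)


def _vcf_header(reference: Mapping[str, str], info_lines: List[Tuple[str, str, str, str]]):
    import pysam

    header = pysam.VariantHeader()
    for chrom, seq in reference.items():
        header.contigs.add(chrom, length=len(seq))
    for name, number, vtype, desc in info_lines:
        header.info.add(name, number, vtype, desc)
    return header


def write_population_vcf(calls: Sequence[SnpCall], reference: Mapping[str, str], path) -> None:
    """One uncompressed VCF per population with read counts and MAF in INFO."""
    import pysam

    header = _vcf_header(
        reference,
        [
            ("RC", "1", "Integer", "Reference allele read count"),
            ("AC", "1", "Integer", "Alternate allele read count"),
            ("MAF", "1", "Float", "Minor allele frequency by read counting"),
            ("CQ", "1", "Float", "Consensus quality"),
            ("BMQ", "1", "Integer", "Best mapping quality at site"),
        ],
    )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            rec = out.new_record(
                contig=c.chrom,
                start=c.pos,
                stop=c.pos + 1,
                alleles=(c.ref_allele, c.alt_allele),
            )
            rec.info["RC"] = c.ref_count
            rec.info["AC"] = c.alt_count
            rec.info["MAF"] = c.maf
            rec.info["CQ"] = c.consensus_quality
            rec.info["BMQ"] = c.best_mapq
            out.write(rec)


def write_merged_vcf(merged: Sequence[MergedSnp], reference: Mapping[str, str], path) -> None:
    import pysam

    header = _vcf_header(
        reference,
        [
            ("NPOP", "1", "Integer", "Number of populations detecting the SNP"),
            ("MAF", "1", "Float", "Count-weighted overall minor allele frequency"),
            ("KNOWN", "0", "Flag", "Present in the known-SNP table"),
            ("CONFLICT", "0", "Flag", "Allele pair differs between populations"),
            ("POPS", ".", "String", "Detecting populations"),
        ],
    )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for m in sorted(merged, key=lambda m: (m.chrom, m.pos)):
            rec = out.new_record(
                contig=m.chrom,
                start=m.pos,
                stop=m.pos + 1,
                alleles=(m.ref_allele, m.alt_allele),
            )
            rec.info["NPOP"] = m.n_populations_detected
            rec.info["MAF"] = m.overall_maf
            if m.known:
                rec.info["KNOWN"] = True
            if m.allele_conflict:
                rec.info["CONFLICT"] = True
            rec.info["POPS"] = ",".join(sorted(m.calls))
            out.write(rec)


def read_vcf_calls(path, population_id: str) -> List[SnpCall]:
    """Round-trip reader for per-population VCFs."""
    import pysam

    calls: List[SnpCall] = []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            calls.append(
                SnpCall(
                    population_id,
                    rec.chrom,
                    rec.start,
                    rec.ref,
                    rec.alts[0],
                    int(rec.info["RC"]),
                    int(rec.info["AC"]),
                    float(rec.info["MAF"]),
                    float(rec.info["CQ"]),
                    int(rec.info["BMQ"]),
                )
            )
    return calls
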