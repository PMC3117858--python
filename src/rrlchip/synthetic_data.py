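"""Synthetic inputs with known ground truth for the whole pipeline.

The generators emulate the study design behind a pooled, reduced-
representation SNP discovery project in a bird genome:

* a genome of macro- and micro-chromosomes (micro-chromosomes GC-rich)
  plus unplaced contigs and a mitochondrion;
* planted biallelic SNPs with a configurable, by default flat, high-MAF
  spectrum, with per-population alternate-allele frequencies;
* pooled-DNA sequencing: 36 bp paired-end reads whose templates are drawn
  i.i.d. from the 2N founder haplotypes of each pool, starting at the blunt
  AluI cut so first-in-pair reads begin with "CT";
* assay design scores (a stand-in for a commercial design tool — only the
  0.6 acceptance threshold matters downstream);
* full-sib mapping families with Mendelian transmission and interference-
  free (Haldane) crossovers.

Every generator is deterministic for a fixed seed, and every artifact can
be serialised to plain-text formats (FASTA, FASTQ, TSV) alongside its truth
table so downstream recovery is assertable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .rrl_design import FragmentInventory, SizeWindow, reverse_complement

__all__ = [
    "SIZE_CLASSES",
    "Chromosome",
    "SyntheticGenome",
    "TruthSnp",
    "PoolSpec",
    "FamilyDesign",
    "generate_genome",
    "plant_snps",
    "simulate_pool_reads",
    "assign_design_scores",
    "simulate_family_genotypes",
    "write_fasta",
    "read_fasta",
    "truth_snps_to_frame",
]

SIZE_CLASSES = ("macro", "intermediate", "micro", "unplaced_contig", "mito")

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


@dataclass(frozen=True)
class Chromosome:
    name: str
    sequence: str
    size_class: str

    def __post_init__(self) -> None:
        if self.size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size class {self.size_class!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SyntheticGenome:
    chromosomes: List[Chromosome]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")

    @property
    def total_bp(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def as_dict(self) -> Dict[str, str]:
        return {c.name: c.sequence for c in self.chromosomes}

    def size_class_of(self, name: str) -> str:
        return self[name].size_class


@dataclass(frozen=True)
class TruthSnp:
    """A planted biallelic variant with per-population alt frequencies."""

    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    pop_freq: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for f in self.pop_freq.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("population frequency outside [0, 1]")

    def maf(self, population: str) -> float:
        f = self.pop_freq[population]
        return min(f, 1.0 - f)


@dataclass(frozen=True)
class PoolSpec:
    """A pooled-DNA sequencing library: N diploids sequenced to a target
    fold-depth over the size-selected fraction."""

    population_id: str
    n_individuals: int = 25
    target_depth: float = 30.0

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")


@dataclass
class FamilyDesign:
    """Full-sib mapping family layout with a truth genetic map.

    ``marker_map`` maps marker id -> (chrom, cM position).  cM positions
    must be nondecreasing within a chromosome when markers are listed in
    map order.
    """

    n_families: int
    offspring_per_family: int
    founder_freq: Mapping[str, float]  # marker -> allele-A frequency
    marker_map: Mapping[str, Tuple[str, float]]

    def __post_init__(self) -> None:
        if self.n_families <= 0 or self.offspring_per_family <= 0:
            raise ValueError("family and offspring counts must be positive")
        for chrom, markers in self.markers_by_chrom().items():
            cms = [self.marker_map[m][1] for m in markers]
            if any(b < a for a, b in zip(cms, cms[1:])):
                raise ValueError(f"{chrom}: cM positions must be nondecreasing")

    def markers_by_chrom(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for m, (chrom, cm) in self.marker_map.items():
            out.setdefault(chrom, []).append(m)
        for chrom in out:
            out[chrom].sort(key=lambda m: self.marker_map[m][1])
        return out


# ---------------------------------------------------------------------------
# genome


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(_BASES[idx])


def generate_genome(
    sizes: Mapping[str, Sequence[int]],
    gc_bias: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> SyntheticGenome:
    """Generate a genome with named size classes and per-class GC content.

    ``sizes`` maps a size class (macro, intermediate, micro, unplaced_contig,
    mito) to a list of chromosome lengths in bp.  ``gc_bias`` maps a class to
    its target GC fraction; the default is 0.42 for macro-chromosomes rising
    to 0.52 for micro-chromosomes, mirroring the GC enrichment of small,
    gene-dense avian chromosomes.
    """
    defaults = {
        "macro": 0.42,
        "intermediate": 0.46,
        "micro": 0.52,
        "unplaced_contig": 0.52,
        "mito": 0.45,
    }
    gc = dict(defaults)
    if gc_bias:
        gc.update(gc_bias)
    rng = np.random.default_rng(seed)
    prefix = {
        "macro": "chr_macro",
        "intermediate": "chr_int",
        "micro": "chr_micro",
        "unplaced_contig": "contig",
        "mito": "chrMT",
    }
    chroms: List[Chromosome] = []
    for cls in SIZE_CLASSES:
        for i, size in enumerate(sizes.get(cls, []), start=1):
            if size <= 0:
                raise ValueError(f"{cls}: chromosome size must be positive")
            name = f"{prefix[cls]}{i}" if cls != "mito" else prefix[cls]
            chroms.append(Chromosome(name, _random_sequence(rng, int(size), gc[cls]), cls))
    return SyntheticGenome(chroms)


# ---------------------------------------------------------------------------
# truth SNPs


def plant_snps(
    genome: SyntheticGenome,
    density: float,
    maf_spectrum: Tuple[float, float] = (0.15, 0.5),
    populations: Sequence[str] = ("B1", "B2", "BL", "WL"),
    seed: int = 0,
    share: float = 0.0,
) -> List[TruthSnp]:
    """Plant biallelic SNPs at random positions with a flat MAF spectrum.

    ``density`` is expected SNPs per bp; per-chromosome counts are Poisson.
    ``maf_spectrum`` = (lo, hi) draws each SNP's minor allele frequency
    uniformly on [lo, hi] (0 < lo <= hi <= 0.5); the alt allele is placed on
    the minor or major side with equal probability.  Frequencies are drawn
    independently per population unless ``share`` > 0, in which case each
    SNP reuses one draw across all populations with probability ``share``.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    lo, hi = maf_spectrum
    if not 0 < lo <= hi <= 0.5:
        raise ValueError("maf_spectrum must satisfy 0 < lo <= hi <= 0.5")
    rng = np.random.default_rng(seed)
    snps: List[TruthSnp] = []
    for chrom in genome.chromosomes:
        n = rng.poisson(density * len(chrom))
        if n == 0:
            continue
        if n > len(chrom):
            raise ValueError(f"{chrom.name}: SNP density too high for length")
        positions = np.sort(rng.choice(len(chrom), size=n, replace=False))
        for pos in positions:
            ref = chrom.sequence[pos]
            if ref == "N":
                continue
            alt = rng.choice([b for b in "ACGT" if b != ref])
            shared_maf = float(rng.uniform(lo, hi))
            shared_flip = bool(rng.random() < 0.5)
            use_shared = rng.random() < share
            freqs: Dict[str, float] = {}
            for pop in populations:
                if use_shared:
                    m, flip = shared_maf, shared_flip
                else:
                    m, flip = float(rng.uniform(lo, hi)), bool(rng.random() < 0.5)
                freqs[pop] = 1.0 - m if flip else m
            snps.append(TruthSnp(chrom.name, int(pos), ref, str(alt), freqs))
    return snps


def truth_snps_to_frame(snps: Iterable[TruthSnp]) -> pd.DataFrame:
    """Serialisable truth table: one row per SNP, one freq column per pop."""
    rows = []
    for s in snps:
        row = {"chrom": s.chrom, "pos": s.pos, "ref": s.ref_allele, "alt": s.alt_allele}
        row.update({f"freq_{p}": f for p, f in s.pop_freq.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pooled reads


def simulate_pool_reads(
    genome: SyntheticGenome,
    truth_snps: Sequence[TruthSnp],
    fragments: FragmentInventory,
    window: SizeWindow,
    pool: PoolSpec,
    read_len: int = 36,
    error_rate: float = 0.0,
    quality_high: int = 40,
    quality_low: int = 8,
    p_low_quality_read: float = 0.0,
    seed: int = 0,
) -> Tuple[List[Tuple[str, str, str]], List[Tuple[str, str, str]]]:
    """Simulate paired 36 bp reads from the size-selected fragments of a pool.

    Each read pair picks a selected fragment (probability proportional to
    fragment length) and a template haplotype drawn i.i.d. from the pool's
    2N founder haplotypes; haplotype alleles at planted SNPs are Bernoulli
    draws from the population alt frequency, fixed once per pool.  Read 1 is
    the first ``read_len`` bases of the fragment; read 2 the first
    ``read_len`` bases of its reverse complement — on blunt AG^CT fragments
    both therefore start with "CT".  Pair count is set so that total read
    bases = target_depth x selected bp.

    Returns (reads1, reads2), each a list of (id, sequence, quality string);
    mate ids carry the conventional /1 and /2 suffixes.
    """
    sel_bed, selected_bp, _ = _select(fragments, window)
    if selected_bp == 0:
        raise ValueError("no template: size window selects no fragments")
    rng = np.random.default_rng(seed)
    n_hap = 2 * pool.n_individuals

    # realised pool haplotypes at each truth SNP (one Binomial(2N, f) draw)
    frag_snps: Dict[int, List[Tuple[int, str, str, np.ndarray]]] = {}
    frag_rows = list(sel_bed.itertuples(index=False))
    by_chrom: Dict[str, List[int]] = {}
    for i, row in enumerate(frag_rows):
        by_chrom.setdefault(row.chrom, []).append(i)
    for s in truth_snps:
        for i in by_chrom.get(s.chrom, []):
            row = frag_rows[i]
            if row.start <= s.pos < row.end:
                f = s.pop_freq[pool.population_id]
                hap_alleles = (rng.random(n_hap) < f).astype(bool)
                frag_snps.setdefault(i, []).append(
                    (s.pos - row.start, s.ref_allele, s.alt_allele, hap_alleles)
                )

    n_pairs = int(round(pool.target_depth * selected_bp / (2 * read_len)))
    lengths = np.array([r.end - r.start for r in frag_rows], dtype=float)
    frag_choice = rng.choice(len(frag_rows), size=n_pairs, p=lengths / lengths.sum())
    hap_choice = rng.integers(0, n_hap, size=n_pairs)
    low_q = rng.random(2 * n_pairs) < p_low_quality_read

    seqs = genome.as_dict()
    reads1: List[Tuple[str, str, str]] = []
    reads2: List[Tuple[str, str, str]] = []
    for k in range(n_pairs):
        row = frag_rows[frag_choice[k]]
        frag = list(seqs[row.chrom][row.start : row.end])
        for off, ref, alt, haps in frag_snps.get(int(frag_choice[k]), []):
            frag[off] = alt if haps[hap_choice[k]] else ref
        frag_s = "".join(frag)
        r1 = frag_s[:read_len]
        r2 = reverse_complement(frag_s)[:read_len]
        if error_rate > 0:
            r1 = _apply_errors(rng, r1, error_rate)
            r2 = _apply_errors(rng, r2, error_rate)
        # id encodes origin (population:serial:chrom:fragment_start) so
        # truth-based assertions can recover the template locus
        rid = f"{pool.population_id}:{k}:{row.chrom}:{row.start}"
        q1 = _qual_string(len(r1), quality_low if low_q[2 * k] else quality_high)
        q2 = _qual_string(len(r2), quality_low if low_q[2 * k + 1] else quality_high)
        reads1.append((rid + "/1", r1, q1))
        reads2.append((rid + "/2", r2, q2))
    return reads1, reads2


def _select(fragments: FragmentInventory, window: SizeWindow):
    from .rrl_design import select_fraction

    return select_fraction(fragments, window)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


def _qual_string(length: int, q: int) -> str:
    return chr(q + 33) * length


def write_fastq(reads: Iterable[Tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# design scores


def assign_design_scores(
    snp_ids: Sequence[str],
    spec: str = "uniform",
    seed: int = 0,
) -> Dict[str, float]:
    """Assign each SNP an assay design score in [0, 1].

    ``spec`` is "uniform" (scores ~ U[0,1]), "all_ones", or "beta:a,b".
    Only the downstream >= 0.6 acceptance threshold gives these meaning.
    """
    rng = np.random.default_rng(seed)
    n = len(snp_ids)
    if spec == "all_ones":
        scores = np.ones(n)
    elif spec == "uniform":
        scores = rng.uniform(0.0, 1.0, size=n)
    elif spec.startswith("beta:"):
        a, b = (float(x) for x in spec[5:].split(","))
        scores = rng.beta(a, b, size=n)
    else:
        raise ValueError(f"unknown design-score spec {spec!r}")
    return {sid: float(s) for sid, s in zip(snp_ids, scores)}


# ---------------------------------------------------------------------------
# mapping families


def _haldane_theta(d_cm: float) -> float:
    """Recombination fraction for an interference-free (Haldane) interval."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cm / 100.0))


def simulate_family_genotypes(
    design: FamilyDesign,
    seed: int = 0,
    min_het_parents: int = 0,
) -> pd.DataFrame:
    """Simulate full-sib family genotypes under Mendelian transmission.

    Founders are drawn in Hardy-Weinberg proportions from the per-marker
    allele-A frequency.  Gametes are generated chromosome by chromosome:
    the haplotype phase of each parent is random, and crossovers between
    adjacent markers occur without interference at the Haldane recombination
    fraction implied by the cM gap; different chromosomes segregate
    independently.

    ``min_het_parents`` > 0 redraws each marker's founder alleles until at
    least that many parents are heterozygous, emulating a mapping panel
    restricted to markers known to segregate in the families (a marker with
    no heterozygous parent yields no informative meioses and cannot be
    placed by linkage at all).

    Returns a PED-like table: columns family, individual, sire, dam, role,
    then one column per marker with genotypes "AA", "AB" or "BB".
    """
    for m in design.founder_freq:
        if m not in design.marker_map:
            raise ValueError(f"marker {m!r} has no map position")
    n_parents = 2 * design.n_families
    if min_het_parents > n_parents:
        raise ValueError("min_het_parents exceeds the number of parents")
    rng = np.random.default_rng(seed)
    by_chrom = design.markers_by_chrom()
    marker_order = [m for chrom in sorted(by_chrom) for m in by_chrom[chrom]]

    # founder haplotypes: per marker an (n_parents, 2) allele matrix
    # (0 = A, 1 = B), optionally conditioned on segregation
    founder_hap: Dict[str, np.ndarray] = {}
    for m in marker_order:
        while True:
            alleles = (rng.random((n_parents, 2)) >= design.founder_freq[m]).astype(int)
            if (alleles.sum(axis=1) == 1).sum() >= min_het_parents:
                break
        founder_hap[m] = alleles

    def founder_haplotypes(parent_idx: int) -> Dict[str, np.ndarray]:
        return {m: founder_hap[m][parent_idx] for m in marker_order}

    def gamete(hap: Dict[str, np.ndarray]) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for chrom, markers in by_chrom.items():
            phase = rng.integers(0, 2)
            prev_cm = None
            for m in markers:
                cm = design.marker_map[m][1]
                if prev_cm is not None:
                    if rng.random() < _haldane_theta(cm - prev_cm):
                        phase = 1 - phase
                out[m] = int(hap[m][phase])
                prev_cm = cm
        return out

    def geno_str(a: int, b: int) -> str:
        return {0: "AA", 1: "AB", 2: "BB"}[a + b]

    rows = []
    for fam in range(1, design.n_families + 1):
        sire = founder_haplotypes(2 * (fam - 1))
        dam = founder_haplotypes(2 * (fam - 1) + 1)
        fam_id = f"fam{fam}"
        rows.append(
            {"family": fam_id, "individual": f"{fam_id}_sire", "sire": "0", "dam": "0",
             "role": "sire", **{m: geno_str(*sire[m]) for m in marker_order}}
        )
        rows.append(
            {"family": fam_id, "individual": f"{fam_id}_dam", "sire": "0", "dam": "0",
             "role": "dam", **{m: geno_str(*dam[m]) for m in marker_order}}
        )
        for o in range(1, design.offspring_per_family + 1):
            gs, gd = gamete(sire), gamete(dam)
            rows.append(
                {"family": fam_id, "individual": f"{fam_id}_o{o}",
                 "sire": f"{fam_id}_sire", "dam": f"{fam_id}_dam", "role": "offspring",
                 **{m: geno_str(gs[m], gd[m]) for m in marker_order}}
            )
    return pd.DataFrame(rows)


def two_group_family_design(
    n_markers: Tuple[int, int] = (15, 13),
    spacing_cm: float = 5.0,
    n_families: int = 2,
    offspring_per_family: int = 46,
    founder_freq: float = 0.5,
) -> Tuple[FamilyDesign, Dict[str, List[str]]]:
    """The standard hidden-linkage-group scenario.

    Markers are laid out on two chromosomes absent from the reference
    (stand-ins for unassembled micro-chromosomes), evenly spaced at
    ``spacing_cm``; two full-sib families of ``offspring_per_family``
    offspring give 2 x 46 = 92 informative individuals by default.
    Returns the design and the truth partition (chromosome -> marker ids).
    """
    marker_map: Dict[str, Tuple[str, float]] = {}
    truth: Dict[str, List[str]] = {}
    for g, n in enumerate(n_markers, start=1):
        chrom = f"hidden{g}"
        ids = [f"lg{g}_m{i}" for i in range(1, n + 1)]
        truth[chrom] = ids
        for i, mid in enumerate(ids):
            marker_map[mid] = (chrom, i * spacing_cm)
    design = FamilyDesign(
        n_families=n_families,
        offspring_per_family=offspring_per_family,
        founder_freq={m: founder_freq for m in marker_map},
        marker_map=marker_map,
    )
    return design, truth


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed)


def write_fasta(genome: SyntheticGenome, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(c.sequence), id=c.name, description=f"size_class={c.size_class}")
        for c in genome.chromosomes
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> Dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
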