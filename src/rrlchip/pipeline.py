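"""End-to-end discovery pipeline glue.

Chains the individual modules into the canonical run: digest the genome,
size-select, simulate (or accept) pooled reads per population, apply the
read filters, map, screen over-represented start sites, pile up, call
SNPs, and merge across populations.  Exists so tests, examples and
reproduction scripts exercise one code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .read_qc import (
    QcReport,
    ReadRecord,
    filter_overrepresented_sites,
    run_read_filters,
)
from .rrl_design import ALU_I, FragmentInventory, RestrictionEnzyme, SizeWindow, digest, select_fraction
from .snp_discovery import (
    Alignment,
    MergedSnp,
    Pileup,
    SnpCall,
    build_pileup,
    call_snps,
    map_reads,
    merge_populations,
)
from .synthetic_data import PoolSpec, SyntheticGenome, TruthSnp, simulate_pool_reads

__all__ = ["PopulationResult", "DiscoveryResult", "run_discovery"]


@dataclass
class PopulationResult:
    population_id: str
    qc_report: QcReport
    map_counts: Dict[str, int]
    n_overrepresented_removed: int
    pileup: Pileup
    mean_depth: float
    calls: List[SnpCall]
    rejects: Dict[str, int]


@dataclass
class DiscoveryResult:
    fragments: FragmentInventory
    selected_bp: int
    fraction_selected: float
    populations: Dict[str, PopulationResult]
    merged: List[MergedSnp]
    summary: Dict[str, object]


def run_discovery(
    genome: SyntheticGenome,
    truth_snps: Sequence[TruthSnp],
    window: SizeWindow,
    pools: Sequence[PoolSpec],
    enzyme: RestrictionEnzyme = ALU_I,
    error_rate: float = 0.0,
    p_low_quality_read: float = 0.0,
    known_table: Optional[Set[Tuple[str, int]]] = None,
    seed: int = 0,
) -> DiscoveryResult:
    """Run the full per-population discovery and cross-population merge.

    Each pool's reads are simulated with a seed offset from ``seed`` so
    populations are independent but the whole run is reproducible.
    """
    inventory = digest(genome, enzyme)
    _, selected_bp, fraction = select_fraction(inventory, window)
    reference = genome.as_dict()
    populations: Dict[str, PopulationResult] = {}
    calls_by_pop: Dict[str, List[SnpCall]] = {}
    for i, pool in enumerate(pools):
        r1, r2 = simulate_pool_reads(
            genome,
            truth_snps,
            inventory,
            window,
            pool,
            error_rate=error_rate,
            p_low_quality_read=p_low_quality_read,
            seed=seed * 1000 + i,
        )
        reads = [ReadRecord.from_fastq_tuple(*t) for t in r1 + r2]
        kept, report = run_read_filters(reads)
        tuples = [
            (r.id, r.sequence, "".join(chr(q + 33) for q in r.qualities))
            for r in kept
        ]
        alignments, map_counts = map_reads(tuples, reference)
        pileup = build_pileup(alignments, reference)
        mean_depth = pileup.mean_depth()
        starts = [(a.chrom, a.pos, a.strand) for a in alignments]
        kept_idx, n_removed = filter_overrepresented_sites(starts, mean_depth)
        if n_removed:
            alignments = [alignments[i] for i in kept_idx]
            pileup = build_pileup(alignments, reference)
            mean_depth = pileup.mean_depth()
        calls, rejects = call_snps(
            pileup, reference, pool.population_id, mean_depth=mean_depth
        )
        calls_by_pop[pool.population_id] = calls
        populations[pool.population_id] = PopulationResult(
            pool.population_id,
            report,
            map_counts,
            n_removed,
            pileup,
            mean_depth,
            calls,
            rejects,
        )
    merged, summary = merge_populations(calls_by_pop, known_table)
    return DiscoveryResult(
        inventory, selected_bp, fraction, populations, merged, summary
    )
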