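"""Two-point linkage placement of unmapped markers in full-sib families.

Given genotypes of full-sib families at biallelic markers, a meiosis is
informative for a marker pair when a parent is heterozygous at both
markers and the transmitted allele can be resolved at each (the other
parent's genotype disambiguates; double-heterozygote offspring of two
heterozygous parents are uninformative and contribute nothing).  With the
parental phase chosen per parent to maximise the two-point likelihood, R
recombinants out of N informative meioses give

    theta_hat = min(R/N, 0.5)
    LOD = log10[ theta^R (1-theta)^(N-R) / 0.5^N ]   at theta_hat < 0.5,
    LOD = 0                                          at theta_hat = 0.5.

Unmapped markers are assigned to a chromosome when multiple mapped markers
on that chromosome (and no other) exceed the LOD threshold; the remaining
markers are clustered into new linkage groups as connected components of
the LOD > 4 graph.  Distances are reported with the Kosambi map function
d = 25 ln[(1+2θ)/(1−2θ)] cM, and within-group order comes from greedy
two-point chaining.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "mendelian_check",
    "TwoPointResult",
    "twopoint",
    "twopoint_from_counts",
    "assign_to_chromosome",
    "LinkageGroup",
    "build_new_groups",
    "kosambi_cm",
    "kosambi_theta",
    "order_group",
]

GENOTYPES = ("AA", "AB", "BB")


# ---------------------------------------------------------------------------
# Mendelian screening


def _gametes(geno: Optional[str]) -> Set[str]:
    if geno is None or geno == "missing":
        return {"A", "B"}
    return set(geno)


def _compatible(offspring: str, sire: Optional[str], dam: Optional[str]) -> bool:
    """Offspring genotype achievable from some sire x dam gamete pair."""
    target = tuple(sorted(offspring))
    return any(
        tuple(sorted((a, b))) == target
        for a in _gametes(sire)
        for b in _gametes(dam)
    )


def mendelian_check(
    genotypes: pd.DataFrame, markers: Optional[Sequence[str]] = None
) -> Tuple[pd.DataFrame, List[Tuple[str, str, str]]]:
    """Screen offspring genotypes for Mendelian inconsistencies.

    ``genotypes`` is the PED-like table produced by the family simulator
    (columns family, individual, sire, dam, role, then one column per
    marker with 'AA'/'AB'/'BB'/'missing').  An offspring genotype that
    cannot arise from the parental pair (missing parents unconstrained) is
    set to 'missing' and reported as (family, individual, marker).
    """
    meta_cols = ["family", "individual", "sire", "dam", "role"]
    if markers is None:
        markers = [c for c in genotypes.columns if c not in meta_cols]
    cleaned = genotypes.copy()
    errors: List[Tuple[str, str, str]] = []
    for fam, grp in genotypes.groupby("family"):
        parents = {row["role"]: row for _, row in grp.iterrows() if row["role"] in ("sire", "dam")}
        for idx, row in grp.iterrows():
            if row["role"] != "offspring":
                continue
            for m in markers:
                g = row[m]
                if g == "missing":
                    continue
                sire_g = parents["sire"][m] if "sire" in parents else None
                dam_g = parents["dam"][m] if "dam" in parents else None
                if not _compatible(g, sire_g, dam_g):
                    cleaned.at[idx, m] = "missing"
                    errors.append((fam, row["individual"], m))
    return cleaned, errors


# ---------------------------------------------------------------------------
# two-point estimation


@dataclass(frozen=True)
class TwoPointResult:
    marker_a: str
    marker_b: str
    theta_hat: float
    lod: float
    n_informative_meioses: int


def _lod(r: int, n: int) -> Tuple[float, float]:
    theta = min(r / n, 0.5)
    if theta >= 0.5:
        return 0.5, 0.0
    if theta == 0.0:
        return 0.0, n * math.log10(2.0)
    lod = (
        r * math.log10(theta)
        + (n - r) * math.log10(1.0 - theta)
        + n * math.log10(2.0)
    )
    return theta, lod


def twopoint_from_counts(
    marker_a: str, marker_b: str, recombinants: int, informative: int
) -> TwoPointResult:
    """Closed-form two-point result from phase-known meiosis counts."""
    if informative <= 0:
        raise ValueError("need at least one informative meiosis")
    theta, lod = _lod(recombinants, informative)
    return TwoPointResult(marker_a, marker_b, theta, lod, informative)


def _transmitted(offspring: str, het_parent_other: Optional[str]) -> Optional[str]:
    """Allele transmitted by a heterozygous parent, or None if unresolvable.

    ``het_parent_other`` is the other parent's genotype.
    """
    if offspring == "missing":
        return None
    if offspring == "AA":
        return "A"
    if offspring == "BB":
        return "B"
    # offspring AB: resolved only if the other parent is homozygous
    if het_parent_other == "AA":
        return "B"
    if het_parent_other == "BB":
        return "A"
    return None


def _transmission_vectors(
    genotypes: pd.DataFrame, markers: Sequence[str]
) -> List[Dict[str, Dict[str, np.ndarray]]]:
    """Resolved transmissions, coded 0=A, 1=B, -1=unknown.

    One dict per family mapping parent role ('sire'/'dam') to, for each
    marker at which that parent is heterozygous, the allele it transmitted
    to each offspring (offspring order fixed within the family).
    """
    out: List[Dict[str, Dict[str, np.ndarray]]] = []
    code = {"A": 0, "B": 1, None: -1}
    for fam, grp in genotypes.groupby("family"):
        parents = {row["role"]: row for _, row in grp.iterrows() if row["role"] in ("sire", "dam")}
        offspring = grp[grp["role"] == "offspring"]
        fam_vecs: Dict[str, Dict[str, np.ndarray]] = {}
        for role, other_role in (("sire", "dam"), ("dam", "sire")):
            if role not in parents:
                continue
            parent = parents[role]
            other = parents.get(other_role)
            vecs: Dict[str, np.ndarray] = {}
            for m in markers:
                if parent[m] != "AB":
                    continue
                other_g = other[m] if other is not None else None
                vecs[m] = np.array(
                    [code[_transmitted(g, other_g)] for g in offspring[m]],
                    dtype=np.int8,
                )
            if vecs:
                fam_vecs[role] = vecs
        if fam_vecs:
            out.append(fam_vecs)
    return out


def _pair_counts(
    fam_vecs: Sequence[Dict[str, Dict[str, np.ndarray]]], a: str, b: str
) -> List[Tuple[int, int]]:
    """Per-parent (recombinant, informative) counts for one marker pair.

    When both parents of a family are heterozygous at both markers, a
    meiosis pair is only resolvable for offspring homozygous at both
    markers — there the two transmitted gametes are forced identical, so
    the observed pattern frequencies mix both parents' unknown phases and
    carry no clean single-parent recombination signal.  Such double-
    intercross configurations contribute no meioses (an extension of the
    rule that AB x AB matings with AB offspring are uninformative).
    """
    counts: List[Tuple[int, int]] = []
    for fam in fam_vecs:
        masks: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for role, vecs in fam.items():
            if a in vecs and b in vecs:
                ta, tb = vecs[a], vecs[b]
                masks[role] = ((ta >= 0) & (tb >= 0), ta, tb)
        if "sire" in masks and "dam" in masks:
            # Double-intercross: only double-homozygous offspring resolve,
            # and there the two gametes are identical — one observation,
            # counted once (the dam's copy is dropped).
            sm = masks["sire"][0]
            masks["dam"] = (masks["dam"][0] & ~sm, masks["dam"][1], masks["dam"][2])
        for mask, ta, tb in masks.values():
            n = int(mask.sum())
            if n == 0:
                continue
            r = int((ta[mask] != tb[mask]).sum())
            counts.append((r, n))
    return counts


def twopoint_all(
    genotypes: pd.DataFrame,
    markers: Sequence[str],
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
) -> List[TwoPointResult]:
    """Two-point results for marker pairs, vectorised over offspring.

    For each parent heterozygous at both markers, the transmitted alleles
    of each offspring are resolved where possible (the other parent's
    genotype disambiguates heterozygous offspring); the parental phase is
    the one minimising recombinants for that parent (the maximum-likelihood
    phase at theta < 0.5).  Per-parent counts are summed and folded into
    the closed-form binomial likelihood-ratio LOD.  Pairs with no
    informative meiosis are omitted.
    """
    vectors = _transmission_vectors(genotypes, markers)
    if pairs is None:
        pairs = [
            (markers[i], markers[j])
            for i in range(len(markers))
            for j in range(i + 1, len(markers))
        ]
    results: List[TwoPointResult] = []
    for a, b in pairs:
        counts = _pair_counts(vectors, a, b)
        r_total = sum(min(r, n - r) for r, n in counts)
        n_total = sum(n for _, n in counts)
        if n_total == 0:
            continue
        theta, lod = _lod(r_total, n_total)
        results.append(TwoPointResult(a, b, theta, lod, n_total))
    return results


def twopoint(
    marker_a: str, marker_b: str, genotypes: pd.DataFrame
) -> Optional[TwoPointResult]:
    """Two-point linkage between one marker pair over full-sib families.

    See :func:`twopoint_all` for the estimation rules.  Returns None when
    no meiosis is informative (distinguishable from a LOD of 0).
    """
    results = twopoint_all(genotypes, [marker_a, marker_b], pairs=[(marker_a, marker_b)])
    return results[0] if results else None


# ---------------------------------------------------------------------------
# chromosome assignment and new groups


def assign_to_chromosome(
    results: Sequence[TwoPointResult],
    mapped_chromosome: Mapping[str, str],
    lod_threshold: float = 4.0,
    min_support: int = 2,
) -> Tuple[Optional[str], bool]:
    """Place an unmapped marker using its two-point results to mapped markers.

    ``results`` are the two-point results of one unmapped marker against
    mapped markers; ``mapped_chromosome`` maps mapped marker id ->
    chromosome.  The marker is assigned to chromosome C iff at least
    ``min_support`` markers on C exceed the LOD threshold and no other
    chromosome qualifies.  Returns (chromosome or None, conflict flag).
    """
    support: Dict[str, int] = {}
    for res in results:
        partner = res.marker_b if res.marker_b in mapped_chromosome else res.marker_a
        if partner not in mapped_chromosome:
            continue
        if res.lod > lod_threshold:
            chrom = mapped_chromosome[partner]
            support[chrom] = support.get(chrom, 0) + 1
    qualifying = [c for c, n in support.items() if n >= min_support]
    if len(qualifying) == 1:
        return qualifying[0], False
    return None, len(qualifying) > 1


@dataclass
class LinkageGroup:
    label: str
    members: List[str]
    order: Optional[List[str]] = None
    adjacent_cm: Optional[List[float]] = None


def build_new_groups(
    unassigned: Sequence[str],
    pairwise: Sequence[TwoPointResult],
    lod_threshold: float = 4.0,
) -> List[LinkageGroup]:
    """Cluster unassigned markers into new linkage groups.

    Groups are the connected components of the graph whose edges are pairs
    with LOD strictly above the threshold; singletons are not groups.
    Labels are LG1, LG2, ... by descending size, ties by smallest member id.
    """
    g = nx.Graph()
    g.add_nodes_from(unassigned)
    for res in pairwise:
        if res.marker_a in g and res.marker_b in g and res.lod > lod_threshold:
            g.add_edge(res.marker_a, res.marker_b)
    components = [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]
    components.sort(key=lambda c: (-len(c), c[0]))
    return [
        LinkageGroup(f"LG{i}", members)
        for i, members in enumerate(components, start=1)
    ]


# ---------------------------------------------------------------------------
# Kosambi map function


def kosambi_cm(theta: float) -> float:
    """Kosambi map distance d = 25 ln[(1+2θ)/(1−2θ)] cM, for θ in [0, 0.5)."""
    if not 0.0 <= theta < 0.5:
        raise ValueError("theta must be in [0, 0.5)")
    return 25.0 * math.log((1.0 + 2.0 * theta) / (1.0 - 2.0 * theta))


def kosambi_theta(d_cm: float) -> float:
    """Inverse Kosambi: θ = tanh(2d/100) / 2; round-trips with kosambi_cm."""
    if d_cm < 0:
        raise ValueError("distance must be nonnegative")
    return 0.5 * math.tanh(2.0 * d_cm / 100.0)


# ---------------------------------------------------------------------------
# ordering


def order_group(
    group: LinkageGroup, pairwise: Sequence[TwoPointResult]
) -> LinkageGroup:
    """Order a linkage group by greedy two-point chaining.

    The chain starts at one end of the most distant confident pair (largest
    theta_hat) and grows by repeatedly appending the unplaced member
    closest (smallest theta_hat) to the current chain end.  Adjacent
    distances are Kosambi-transformed theta estimates.  A two-marker group
    is order-equivalent to its reversal.
    """
    members = set(group.members)
    if len(members) < 2:
        raise ValueError("group must have at least two markers")
    theta: Dict[frozenset, float] = {}
    for res in pairwise:
        if res.marker_a in members and res.marker_b in members:
            theta[frozenset((res.marker_a, res.marker_b))] = res.theta_hat

    def th(a: str, b: str) -> float:
        return theta.get(frozenset((a, b)), 0.5)

    far_pair = max(
        (p for p in theta if len(p) == 2),
        key=lambda p: theta[p],
        default=None,
    )
    if far_pair is None:
        raise ValueError("no pairwise estimates within the group")
    anchor = sorted(far_pair)[0]
    order = [anchor]
    remaining = members - {anchor}
    while remaining:
        end = order[-1]
        nxt = min(sorted(remaining), key=lambda m: th(end, m))
        order.append(nxt)
        remaining.discard(nxt)
    distances = [kosambi_cm(min(th(a, b), 0.4999999)) for a, b in zip(order, order[1:])]
    return LinkageGroup(group.label, group.members, order, distances)
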