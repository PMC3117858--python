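"""Array-performance simulation and the four-class validation partition.

Every SNP on a designed panel ends up in exactly one of four performance
classes once a diverse sample panel has been genotyped:

* ``failed``      — the assay could not be designed/manufactured;
* ``excluded``    — the assay was removed after cluster review (cannot be
  separated into the three genotype clusters, or every call is
  heterozygous — the signature of a paralogue-collapsed "SNP");
* ``monomorphic`` — only one allele observed in any breed, the signature
  of a false-positive discovery;
* ``polymorphic`` — both alleles observed in at least one breed.

``simulate_assay`` provides a genotype-level stand-in for the intensity
assay: design failures and cluster failures are Bernoulli draws, and
genotypes are drawn in Hardy-Weinberg proportions from per-breed allele
frequencies.  ``validation_table`` tabulates class counts and percentages
per SNP group with the reporting convention that the failed percentage is
taken over the whole group while the other three classes are taken over
the SNPs that passed design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeCallSet",
    "simulate_assay",
    "classify_performance",
    "validation_table",
    "validation_table_from_counts",
    "PERFORMANCE_CLASSES",
]

PERFORMANCE_CLASSES = ("failed", "excluded", "monomorphic", "polymorphic")

_CALL_CODES = {"AA": 0, "AB": 1, "BB": 2, "missing": -1}


@dataclass
class GenotypeCallSet:
    """Sample x SNP genotype calls with per-SNP assay status.

    ``calls`` is coded -1 missing / 0 AA / 1 AB / 2 BB, with one row per
    sample; ``breeds`` labels the rows.  Design-failed SNPs carry no calls
    (all missing).
    """

    snp_ids: List[str]
    breeds: List[str]
    calls: np.ndarray  # shape (n_samples, n_snps), int8
    failed_design: np.ndarray  # bool per SNP
    cluster_ok: np.ndarray  # bool per SNP

    def __post_init__(self) -> None:
        n_samples, n_snps = self.calls.shape
        if n_samples != len(self.breeds) or n_snps != len(self.snp_ids):
            raise ValueError("call matrix shape does not match labels")
        if self.calls[:, self.failed_design].max(initial=-1) != -1:
            raise ValueError("design-failed SNPs must have no calls")

    def call_rate(self) -> float:
        designed = ~self.failed_design
        if not designed.any():
            return float("nan")
        sub = self.calls[:, designed]
        return float((sub != -1).mean())

    def to_frame(self) -> pd.DataFrame:
        codes = {v: k for k, v in _CALL_CODES.items()}
        df = pd.DataFrame(
            [[codes[int(v)] for v in row] for row in self.calls],
            columns=self.snp_ids,
        )
        df.insert(0, "breed", self.breeds)
        return df


def simulate_assay(
    snp_ids: Sequence[str],
    breed_freqs: Mapping[str, Sequence[float]],
    samples_per_breed: int = 24,
    p_fail_design: float = 0.0,
    p_cluster_fail: float = 0.0,
    p_missing: float = 0.0,
    seed: int = 0,
) -> GenotypeCallSet:
    """Simulate genotyping of a breed panel over the array content.

    ``breed_freqs`` maps breed -> per-SNP B-allele frequency (length =
    number of SNPs).  Genotypes are Hardy-Weinberg draws; a SNP fails
    design with ``p_fail_design`` and fails cluster review with
    ``p_cluster_fail``; individual calls go missing with ``p_missing``.
    """
    rng = np.random.default_rng(seed)
    n_snps = len(snp_ids)
    for breed, freqs in breed_freqs.items():
        if len(freqs) != n_snps:
            raise ValueError(f"breed {breed!r}: frequency vector length mismatch")
    if not breed_freqs:
        raise ValueError("at least one breed with frequencies is required")
    failed = rng.random(n_snps) < p_fail_design
    cluster_ok = rng.random(n_snps) >= p_cluster_fail
    breeds: List[str] = []
    rows: List[np.ndarray] = []
    for breed in breed_freqs:
        f = np.asarray(breed_freqs[breed], dtype=float)
        for _ in range(samples_per_breed):
            geno = (rng.random(n_snps) < f).astype(np.int8) + (
                rng.random(n_snps) < f
            ).astype(np.int8)
            missing = rng.random(n_snps) < p_missing
            geno[missing] = -1
            geno[failed] = -1
            rows.append(geno)
            breeds.append(breed)
    return GenotypeCallSet(
        list(snp_ids), breeds, np.vstack(rows), failed, cluster_ok
    )


def classify_performance(callset: GenotypeCallSet) -> pd.Series:
    """Assign each SNP its performance class (index = SNP id).

    Order of precedence: failed design; excluded (cluster review failed,
    only-heterozygote calls, or no non-missing call at all); polymorphic
    (both alleles seen in at least one breed); else monomorphic.
    """
    classes: List[str] = []
    breeds = np.asarray(callset.breeds)
    for j, sid in enumerate(callset.snp_ids):
        if callset.failed_design[j]:
            classes.append("failed")
            continue
        col = callset.calls[:, j]
        observed = col[col != -1]
        if not callset.cluster_ok[j] or len(observed) == 0 or (observed == 1).all():
            classes.append("excluded")
            continue
        poly = False
        for breed in set(callset.breeds):
            sub = col[(breeds == breed) & (col != -1)]
            if len(sub) == 0:
                continue
            has_a = ((sub == 0) | (sub == 1)).any()
            has_b = ((sub == 2) | (sub == 1)).any()
            if has_a and has_b:
                poly = True
                break
        classes.append("polymorphic" if poly else "monomorphic")
    return pd.Series(classes, index=list(callset.snp_ids), name="performance")


def validation_table_from_counts(
    counts: Mapping[str, Mapping[str, int]]
) -> pd.DataFrame:
    """Validation table from per-group class counts.

    ``counts`` maps group label -> {class: count}.  Columns: per class a
    count and a percentage to one decimal.  The failed percentage uses the
    whole group as denominator; excluded/monomorphic/polymorphic use the
    SNPs passing design (group total minus failed).  Percentages of an
    empty denominator are left blank (NaN).
    """
    rows = []
    for group, cc in counts.items():
        c = {cls: int(cc.get(cls, 0)) for cls in PERFORMANCE_CLASSES}
        total = sum(c.values())
        passing = total - c["failed"]
        row: Dict[str, object] = {"group": group, "total": total, "passing_design": passing}
        for cls in PERFORMANCE_CLASSES:
            denom = total if cls == "failed" else passing
            row[f"{cls}_n"] = c[cls]
            row[f"{cls}_pct"] = round(100.0 * c[cls] / denom, 1) if denom else float("nan")
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def validation_table(
    classes: pd.Series, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """Tabulate performance per SNP group.

    ``groups`` maps group label -> SNP ids belonging to the group (groups
    may overlap, e.g. an "all" group).
    """
    counts: Dict[str, Dict[str, int]] = {}
    for label, ids in groups.items():
        sub = classes.loc[list(ids)]
        counts[label] = sub.value_counts().to_dict()
    return validation_table_from_counts(counts)
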