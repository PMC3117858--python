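"""Classify array performance over a simulated breed panel.

Simulates genotyping of a 500-SNP panel across four breeds with small
design- and cluster-failure rates, partitions the SNPs into the four
performance classes, and prints the validation table with the standard
percentage conventions (failed over all SNPs; the other classes over the
SNPs passing assay design).
"""

import numpy as np

from rrlchip.chip_validation import classify_performance, simulate_assay, validation_table

rng = np.random.default_rng(7)
n = 500
snp_ids = [f"snp{i}" for i in range(n)]
# half the panel segregates everywhere; half is fixed in some breeds
breed_freqs = {
    breed: np.where(rng.random(n) < 0.85, rng.uniform(0.1, 0.9, n), 0.0)
    for breed in ("broiler_a", "broiler_b", "layer_brown", "layer_white")
}
callset = simulate_assay(
    snp_ids,
    breed_freqs,
    samples_per_breed=24,
    p_fail_design=0.05,
    p_cluster_fail=0.02,
    seed=8,
)
classes = classify_performance(callset)
table = validation_table(classes, {"all": snp_ids})
print(table[["total", "passing_design"] + [f"{c}_pct" for c in
      ("failed", "excluded", "monomorphic", "polymorphic")]].to_string())
print(f"call rate over designed SNPs: {100*callset.call_rate():.1f}%")
# 'polymorphic' is the validation rate: the fraction of designed assays
# that segregate in at least one breed.
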