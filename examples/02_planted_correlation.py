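"""Plant genes with known expression–brightness correlations and recover
them with the correlation stage.

Prints the realized Pearson r for genes planted at rho = +0.5, 0, and
-0.5 in a 500-cell cohort: the positive/negative targets should be
recovered within sampling error (~0.04) and the null gene near zero, with
the planted genes leading the |r| ranking.
"""

import numpy as np

from pigcorr import (
    gene_brightness_correlation,
    generate_counts,
    log_normalize,
    rank_genes,
    scale_genes,
    top_tables,
)
from pigcorr.simulate import PlantedGeneSpec, pigment_to_ynorm

rng = np.random.default_rng(7)
ynorm = pigment_to_ynorm(rng.uniform(0.1, 0.9, 500))

planted = [
    PlantedGeneSpec(gene_id="POSITIVE_G", target_rho=0.5),
    PlantedGeneSpec(gene_id="NULL_G", target_rho=0.0),
    PlantedGeneSpec(gene_id="NEGATIVE_G", target_rho=-0.5),
]
counts, truth = generate_counts(ynorm, planted, n_background_genes=1997, seed=7)
print("calibrated log-mean slopes:")
print(truth[["gene_id", "target_rho", "slope"]].to_string(index=False))

scaled = scale_genes(log_normalize(counts))
corr = gene_brightness_correlation(scaled, ynorm)
planted_r = corr[corr["gene_id"].isin(truth["gene_id"])]
print("\nrealized Pearson r against Ynorm:")
print(planted_r[["gene_id", "r"]].to_string(index=False))

ranked = rank_genes(corr)
print("\ntop 5 of the |r| ranking (planted genes should dominate):")
for g, s in zip(ranked.genes[:5], ranked.stats[:5]):
    print(f"  {g:12s} |r| = {s:.3f}")

pos, neg = top_tables(corr, k=3)
print("\ntop positive correlates:", ", ".join(pos["gene_id"]))
print("top negative correlates:", ", ".join(neg["gene_id"]))
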