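"""Preranked gene-set enrichment on a ranking with one planted set.

A 30-gene set planted at rho = 0.5 concentrates at the top of the |r|
ranking, so its running-sum ES approaches 1, its NES is large and
positive, and its permutation p-value sits at the floor 1/(n_perm+1) —
far below every random decoy set. Note the Benjamini–Hochberg adjusted
value: with 51 tested sets and a permutation floor of ~0.001 it cannot
drop below ~0.05, the resolution limit of a 1000-permutation null.
"""

import numpy as np

from pigcorr import (
    gene_brightness_correlation,
    generate_counts,
    generate_gene_sets,
    log_normalize,
    rank_genes,
    run_gsea,
    scale_genes,
)
from pigcorr.simulate import PlantedGeneSpec, pigment_to_ynorm

rng = np.random.default_rng(1)
ynorm = pigment_to_ynorm(rng.uniform(0.1, 0.9, 500))

members = [f"PIG_{i:02d}" for i in range(30)]
planted = [PlantedGeneSpec(gene_id=g, target_rho=0.5) for g in members]
counts, _ = generate_counts(ynorm, planted, n_background_genes=1970, seed=1)

sets = generate_gene_sets(
    {"PIGMENT_RESPONSE": members}, decoy_sets=50, universe=list(counts.genes), seed=1
)

scaled = scale_genes(log_normalize(counts))
ranked = rank_genes(gene_brightness_correlation(scaled, ynorm))
table = run_gsea(ranked, sets, n_perm=1000, seed=1)

table = table.sort_values("pval")
cols = ["set_name", "size", "es", "nes", "pval", "padj"]
print("top 5 sets by permutation p-value:")
print(table[cols].head(5).to_string(index=False, float_format="%.4f"))

planted_row = table[table["set_name"] == "PIGMENT_RESPONSE"].iloc[0]
print(
    f"\nplanted set: ES={planted_row.es:.3f}, NES={planted_row.nes:.2f}, "
    f"leading edge of {len(planted_row.leading_edge)} genes"
)
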