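"""LD-corrected gene-based association with the effective chi-square.

Simulates a reference genotype panel (5-variant AR(1) LD blocks) and a
GWAS in which 40 genes carry noncentrality-30 signal, then tests every
gene window.
"""

import numpy as np

import dese

config = dese.SimulationConfig(seed=1)
panel, regions = dese.simulate_genotypes(config)
causal = dese.causal_genes(config)
gwas = dese.simulate_gwas(config, regions, causal)

results, gene_data = dese.gene_based_scan(gwas, panel, regions)
ranked = sorted(results.values(), key=lambda r: r.pvalue)

print("top 5 genes by effective-chi-square p-value:")
for r in ranked[:5]:
    flag = "causal" if r.symbol in causal else ""
    print(f"  {r.symbol}  m={r.n_variants}  S={r.statistic:8.1f}  "
          f"a={r.scale:4.2f}  d={r.df:4.2f}  p={r.pvalue:.3e}  {flag}")

adj = dese.adjust_pvalues([r.pvalue for r in ranked], "bh")
n_sig = int(np.sum(adj < 0.05))
sig_set = {r.symbol for r, a in zip(ranked, adj) if a < 0.05}
print(f"significant genes (FDR < 0.05): {n_sig}; "
      f"recall of planted causal genes: {len(sig_set & set(causal))}/{len(causal)}")

# S sums the per-variant 1-df chi-squares; the scale a and df d come
# from moment-matching against the LD matrix, so correlated variants do
# not count twice. A single variant reduces to its own p-value.
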