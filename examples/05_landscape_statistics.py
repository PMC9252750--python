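"""Landscape statistics: category enrichment and phenotype similarity.

Builds a small phenotype x tissue association table with significance
concentrated in one category pair, tests the pair with the
hypergeometric enrichment formula, and ranks phenotypes by the Jaccard
similarity of their associated gene sets.
"""

import pandas as pd

import dese

# 10 phenotypes x 10 tissues; immune phenotypes hit blood tissues
rows = [
    {"phenotype": f"ph{i}", "column": f"t{j}",
     "pvalue": 1e-6 if (i < 3 and j < 3) else 0.9}
    for i in range(10) for j in range(10)
]
table = pd.DataFrame(rows)
phen_cat = {f"ph{i}": ("immune" if i < 3 else "other") for i in range(10)}
tiss_cat = {f"t{j}": ("blood" if j < 3 else "rest") for j in range(10)}

enrichment = dese.category_enrichment(table, phen_cat, tiss_cat)
print(enrichment.to_string(index=False))

# P_HT is the probability of seeing at least k significant tests in an
# n-test category pair when M of all N tests are significant.

target = {"IL2RA", "PTPN22", "CTLA4"}
catalog = {
    "type1_diabetes": {"IL2RA", "PTPN22", "INS"},
    "rheumatoid_arthritis": {"PTPN22", "CTLA4", "HLA-DRB1"},
    "height": {"HMGA2", "GDF5"},
}
print("\nphenotype similarity to the target gene set:")
for s in dese.similarity_ranking(target, catalog):
    print(f"  {s.phenotype_b:22s} jaccard = {s.jaccard:.3f}")
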