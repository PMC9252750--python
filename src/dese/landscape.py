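"""Association-landscape statistics.

Utilities for summarizing a corpus of phenotype x tissue/cell-type
association tests:

* hypergeometric enrichment of significant associations between a
  phenotype category H and a tissue/cell-type category T,

      P_HT = 1 - sum_{x=0}^{k-1} C(M, x) C(N-M, n-x) / C(N, n)

  where N association P-values were computed in total, M of them are
  significant (FDR-adjusted p < 0.05), n fall between the category pair
  and k of those are significant;
* Jaccard similarity of significantly associated gene sets between two
  phenotypes, and ranking a catalog of phenotypes by it;
* Benjamini-Hochberg and Bonferroni multiple-testing adjustment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import lgamma

import numpy as np
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .errors import InvalidCounts

logger = logging.getLogger(__name__)


@dataclass
class CategoryEnrichmentQuery:
    """Counts behind one category-pair enrichment P-value."""

    N: int
    M: int
    n: int
    k: int
    p_ht: float = np.nan


@dataclass(frozen=True)
class PhenotypeSimilarity:
    """Jaccard similarity of two phenotypes' associated gene sets."""

    phenotype_a: str
    phenotype_b: str
    jaccard: float


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeom_enrichment(N: int, M: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric enrichment P-value P_HT.

    Computed as the tail mass P(X >= k) of Hypergeometric(N, M, n) via
    log-gamma binomial coefficients, numerically identical to
    1 - sum_{x<k} pmf(x) but stable for corpus-scale N. k = 0 gives 1
    (the empty sum).
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= k <= min(M, n)):
        raise InvalidCounts(f"invalid counts N={N}, M={M}, n={n}, k={k}")
    if k == 0:
        return 1.0
    log_denom = _log_comb(N, n)
    x = np.arange(k, min(M, n) + 1)
    terms = [
        _log_comb(M, xi) + _log_comb(N - M, n - xi) - log_denom
        for xi in x
        if n - xi <= N - M
    ]
    if not terms:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(terms))))


def jaccard_similarity(genes_a: set, genes_b: set) -> float:
    """Intersection-over-union of two gene sets; two empty sets give 0."""
    union = genes_a | genes_b
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 0")
        return 0.0
    return len(genes_a & genes_b) / len(union)


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg (``bh``) or ``bonferroni`` adjusted P-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if not ((p > 0) & (p <= 1)).all():
        raise ValueError("p-values must lie in (0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(p, method=key)[1]


def category_enrichment(
    assoc_table,
    phenotype_categories: dict[str, str],
    column_categories: dict[str, str],
    alpha: float = 0.05,
):
    """Category-pair enrichment over a phenotype x column P-value table.

    ``assoc_table`` needs columns ``phenotype``, ``column``, ``pvalue``.
    Significance is FDR-adjusted p < ``alpha`` over the whole table
    (N = all tests, M = all significant); for every (phenotype
    category H, column category T) pair, n tests fall between the pair
    and k of them are significant, giving the hypergeometric P_HT.
    Rows with unmapped phenotypes or columns are ignored.
    """
    import pandas as pd

    t = assoc_table.copy()
    t["significant"] = adjust_pvalues(t["pvalue"].to_numpy(), "bh") < alpha
    t["H"] = t["phenotype"].map(phenotype_categories)
    t["T"] = t["column"].map(column_categories)
    t = t.dropna(subset=["H", "T"])
    N = len(t)
    M = int(t["significant"].sum())
    rows = []
    for (h, c), sub in t.groupby(["H", "T"], sort=True):
        n, k = len(sub), int(sub["significant"].sum())
        rows.append(
            {"phenotype_category": h, "column_category": c,
             "N": N, "M": M, "n": n, "k": k,
             "p_ht": hypergeom_enrichment(N, M, n, k)}
        )
    return pd.DataFrame(rows)


def similarity_ranking(
    target_genes: set,
    catalog: dict[str, set],
    top_k: int | None = None,
) -> list[PhenotypeSimilarity]:
    """Rank catalog phenotypes by Jaccard similarity to a target set.

    Descending similarity, ties broken lexicographically by phenotype
    id; the top ``top_k`` entries are returned (all when None).
    """
    if not catalog:
        raise ValueError("catalog is empty")
    scored = [
        PhenotypeSimilarity("target", pid, jaccard_similarity(target_genes, genes))
        for pid, genes in catalog.items()
    ]
    scored.sort(key=lambda s: (-s.jaccard, s.phenotype_b))
    return scored[:top_k] if top_k is not None else scored
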