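"""Driver-tissue estimation by selective expression (DESE).

The framework alternates two steps until the phenotype-associated gene
set stabilizes:

1. *Tissue/cell-type estimation.* Each panel column is scored by a
   one-sided Wilcoxon rank-sum test asking whether the associated genes
   have higher selective-expression z there than the remaining genes.
2. *Conditional gene re-testing.* Genes are re-tested conditional on a
   retained set ordered by selective expression in the current
   top-ranked column, discounting variant chi-squares shared through LD
   with retained genes.

A hierarchical strategy first runs the loop on a bulk tissue panel,
maps the significant tissues (FDR < 0.05) onto unified organ labels,
then re-runs it on the cell-type columns belonging to those organs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .assoc import (
    DEFAULT_R2_CAP,
    DEFAULT_WINDOW_BP,
    GeneAssociationResult,
    GeneData,
    chisq_from_p,
    condition_genes,
    ecs_test,
)
from .errors import DegenerateGroups, EmptyAnalysis, EmptySubset
from .gwas import ReferencePanel, ld_matrix, map_variants_to_genes
from .landscape import adjust_pvalues
from .panel import ExpressionPanel
from .selective import rez_scores

logger = logging.getLogger(__name__)

EXACT_MAX_GROUP = 8


@dataclass
class TissueAssociation:
    """Per-column enrichment result of the associated-gene set."""

    column: str
    statistic: float
    pvalue: float
    fdr_pvalue: float = np.nan
    bonferroni_pvalue: float = np.nan
    rank: int = 0


@dataclass
class DeseConfig:
    """Tunable knobs of the iterative loop."""

    assoc_alpha: float = 0.05      # BH-adjusted threshold defining associated genes
    min_assoc: int = 10            # floor: smallest-p genes kept if fewer pass
    max_iter: int = 10             # conditioning passes
    r2_cap: float = DEFAULT_R2_CAP
    window_bp: int = DEFAULT_WINDOW_BP
    tissue_alpha: float = 0.05     # FDR threshold for the hierarchical stage


@dataclass
class IterationRecord:
    assoc_genes: frozenset[str]
    tissue_table: pd.DataFrame


@dataclass
class DeseRun:
    """Trace and final state of one DESE loop."""

    iterations: list[IterationRecord]
    converged: bool
    tissues: pd.DataFrame
    genes: dict[str, GeneAssociationResult]

    @property
    def top_column(self) -> str:
        return self.tissues.iloc[0]["column"]


def wilcoxon_enrichment(
    gene_z: pd.Series, assoc_genes: set[str], column: str = ""
) -> TissueAssociation:
    """One-sided rank-sum test: associated genes have greater z.

    When both groups have at most 8 members the p-value is computed by
    exact enumeration of all labelings of the observed (mid)ranks, which
    handles ties and returns 1 when every value is tied. Larger groups
    use the normal approximation with tie and continuity corrections.
    """
    assoc = [g for g in gene_z.index if g in assoc_genes]
    rest = [g for g in gene_z.index if g not in assoc_genes]
    if not assoc or not rest:
        raise DegenerateGroups(
            "associated gene set must be a nonempty proper subset of panel genes"
        )
    x = gene_z.loc[assoc].to_numpy(float)
    y = gene_z.loc[rest].to_numpy(float)
    n1, n2 = len(x), len(y)
    u_obs = _u_statistic(x, y)
    if n1 <= EXACT_MAX_GROUP and n2 <= EXACT_MAX_GROUP:
        p = _exact_greater_pvalue(x, y)
    elif np.ptp(np.concatenate([x, y])) == 0:
        p = 1.0  # every observation tied: no evidence either way
    else:
        p = float(
            mannwhitneyu(x, y, alternative="greater", method="asymptotic").pvalue
        )
    return TissueAssociation(column=column, statistic=u_obs, pvalue=min(1.0, p))


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([x, y]))
    w = ranks[: len(x)].sum()
    return float(w - len(x) * (len(x) + 1) / 2.0)


def _exact_greater_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """P(rank-sum >= observed) over all equally likely labelings."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n, n1 = len(pooled), len(x)
    w_obs = ranks[:n1].sum()
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        total += 1
        if ranks[list(combo)].sum() >= w_obs - 1e-9:
            count += 1
    return count / total


def rank_columns(
    z: pd.DataFrame, assoc_genes: set[str]
) -> pd.DataFrame:
    """Wilcoxon-enrich every panel column and rank by ascending p."""
    rows = []
    for col in z.columns:
        t = wilcoxon_enrichment(z[col], assoc_genes, column=col)
        rows.append(t)
    table = pd.DataFrame(
        {
            "column": [t.column for t in rows],
            "statistic": [t.statistic for t in rows],
            "pvalue": [t.pvalue for t in rows],
        }
    )
    table["fdr_pvalue"] = adjust_pvalues(table["pvalue"].to_numpy(), "bh")
    table["bonferroni_pvalue"] = adjust_pvalues(table["pvalue"].to_numpy(), "bonferroni")
    table = table.sort_values(
        ["pvalue", "column"], kind="stable", ignore_index=True
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def gene_based_scan(
    variants: pd.DataFrame,
    panel: ReferencePanel,
    genes,
    min_variants: int = 1,
) -> tuple[dict[str, GeneAssociationResult], dict[str, GeneData]]:
    """Run the ECS test for every gene window with mapped variants.

    Variants are matched to panel rows by chromosome and position; gene
    windows without any matched variant are skipped with a logged count.
    Returns the results plus the per-gene chi-square/LD data needed for
    conditional re-testing.
    """
    assignment, n_unassigned = map_variants_to_genes(variants, genes)
    if n_unassigned:
        logger.info("%d variant(s) fall outside every gene window", n_unassigned)
    panel_lookup = {
        (str(c), int(p)): i for i, (c, p) in enumerate(zip(panel.chrom, panel.pos))
    }
    results: dict[str, GeneAssociationResult] = {}
    data: dict[str, GeneData] = {}
    n_skipped = 0
    chroms = variants["chrom"].to_numpy()
    poss = variants["pos"].to_numpy()
    ps = variants["p"].to_numpy(float)
    for gene in genes:
        idx = assignment.get(gene.symbol, np.array([], dtype=int))
        rows, pvals = [], []
        for i in idx:
            key = (str(chroms[i]), int(poss[i]))
            if key in panel_lookup:
                rows.append(panel_lookup[key])
                pvals.append(ps[i])
        if len(rows) < min_variants or not rows:
            n_skipped += 1
            continue
        rows = np.array(rows, dtype=int)
        ld = ld_matrix(panel, [panel.ids[r] for r in rows])
        res = ecs_test(np.array(pvals), ld, symbol=gene.symbol)
        results[gene.symbol] = res
        data[gene.symbol] = GeneData(
            symbol=gene.symbol,
            chisq=chisq_from_p(np.asarray(pvals, dtype=float)),
            ld=ld.r,
            variant_rows=rows,
        )
    if n_skipped:
        logger.info("%d gene window(s) had no reference-matched variants", n_skipped)
    return results, data


def _assoc_rule(
    pvalues: pd.Series, alpha: float, min_assoc: int
) -> frozenset[str]:
    """Associated genes: BH-adjusted p < alpha, floored at min_assoc genes."""
    adj = pd.Series(adjust_pvalues(pvalues.to_numpy(), "bh"), index=pvalues.index)
    chosen = set(adj.index[adj < alpha])
    if len(chosen) < min_assoc:
        floor = min(min_assoc, len(pvalues) - 1)  # keep a proper subset
        order = pvalues.sort_values(kind="stable").index[:floor]
        chosen = set(order)
    elif len(chosen) == len(pvalues):  # keep a proper subset
        worst = pvalues.loc[list(chosen)].sort_values(kind="stable").index[-1]
        chosen.discard(worst)
    return frozenset(chosen)


def dese_iterate(
    results: dict[str, GeneAssociationResult],
    gene_data: dict[str, GeneData],
    rez: pd.DataFrame,
    panel: ReferencePanel,
    config: DeseConfig | None = None,
) -> DeseRun:
    """Iterate tissue estimation and conditional gene re-testing.

    Each pass ranks all panel columns by enrichment of the current
    associated-gene set, re-tests candidate genes conditional on the
    retained genes ordered by selective expression in the top column,
    and recomputes the associated set from the conditional p-values.
    The loop stops when the set is unchanged between consecutive passes
    (a confirming record is appended, so a converged trace ends with two
    identical gene sets) or after ``max_iter`` conditioning passes.
    """
    config = config or DeseConfig()
    shared = [g for g in rez.index if g in results]
    if not shared:
        raise EmptyAnalysis("no genes shared between association results and panel")
    z = rez.loc[shared]
    current_p = pd.Series({g: results[g].pvalue for g in shared})
    assoc = _assoc_rule(current_p, config.assoc_alpha, config.min_assoc)

    iterations: list[IterationRecord] = []
    converged = False
    cond_results = {g: results[g] for g in shared}
    for _ in range(config.max_iter):
        table = rank_columns(z, set(assoc))
        iterations.append(IterationRecord(assoc, table))
        top = table.iloc[0]["column"]
        retained = sorted(
            assoc,
            key=lambda g: (-z.loc[g, top], cond_results[g].pvalue, g),
        )
        cond_results = condition_genes(
            cond_results, gene_data, panel, retained,
            r2_cap=config.r2_cap, window_bp=config.window_bp,
        )
        cond_p = pd.Series({g: cond_results[g].conditional_pvalue for g in shared})
        new_assoc = _assoc_rule(cond_p, config.assoc_alpha, config.min_assoc)
        if new_assoc == assoc:
            converged = True
            final_table = rank_columns(z, set(new_assoc))
            iterations.append(IterationRecord(new_assoc, final_table))
            break
        assoc = new_assoc
    final_table = iterations[-1].tissue_table if converged else rank_columns(z, set(assoc))
    if not converged and iterations and iterations[-1].assoc_genes != assoc:
        iterations.append(IterationRecord(assoc, final_table))
    return DeseRun(iterations=iterations, converged=converged,
                   tissues=final_table, genes=cond_results)


def hierarchical_estimate(
    results: dict[str, GeneAssociationResult],
    gene_data: dict[str, GeneData],
    tissue_panel: ExpressionPanel,
    celltype_panel: ExpressionPanel,
    panel: ReferencePanel,
    config: DeseConfig | None = None,
    organs: list[str] | None = None,
) -> tuple[DeseRun, DeseRun]:
    """Estimate associated tissues, then cell types of those organs.

    Stage 1 runs DESE on the bulk tissue panel. Tissues significant at
    FDR < ``config.tissue_alpha`` define an organ set through the
    panels' unified organ labels; stage 2 runs DESE on the cell-type
    columns whose organ label falls in that set. An explicit ``organs``
    list overrides the automatic selection; if no tissue is significant,
    all cell types are used and a warning is logged.
    """
    config = config or DeseConfig()
    tissue_z = rez_scores(tissue_panel)
    tissue_run = dese_iterate(results, gene_data, tissue_z, panel, config)

    if organs is not None:
        organ_set = set(organs)
    else:
        sig = tissue_run.tissues[tissue_run.tissues["fdr_pvalue"] < config.tissue_alpha]
        organ_set = {
            tissue_panel.organ[c] for c in sig["column"] if c in tissue_panel.organ
        }
        if not organ_set:
            logger.warning(
                "no tissue significant at FDR < %.3g; using all cell types",
                config.tissue_alpha,
            )
            organ_set = set(celltype_panel.organ.values())

    cols = [c for c in celltype_panel.columns if celltype_panel.organ.get(c) in organ_set]
    if not cols:
        raise EmptySubset(f"no cell-type columns for organs {sorted(organ_set)}")
    sub = ExpressionPanel(
        celltype_panel.values[cols],
        kind="cell_type",
        organ={c: celltype_panel.organ[c] for c in cols if c in celltype_panel.organ},
        provenance={c: celltype_panel.provenance.get(c, {}) for c in cols},
    )
    celltype_z = rez_scores(sub)
    celltype_run = dese_iterate(results, gene_data, celltype_z, panel, config)
    return tissue_run, celltype_run
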