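"""Reference expression-panel construction.

Builds gene x tissue and gene x cell-type expression panels from bulk
counts and single-cell UMI counts:

* CPM normalization within columns and TMM between-sample factors for
  bulk data, followed by per-tissue averaging;
* UMI filtering (cells with fewer than 300 UMIs dropped), cluster-level
  pseudobulk built from the top 10% highest-depth cells, removal of
  small (< 15 cells), unlabeled, or disease-derived clusters, merging of
  same-labeled clusters within a dataset;
* homolog mapping of non-human gene symbols onto HGNC symbols, keeping
  strictly one-to-one pairs.

Counts live in a :class:`CountsMatrix` (genes x samples-or-cells);
finished panels in an :class:`ExpressionPanel` whose columns are CPM
profiles annotated with a unified organ label and provenance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    MissingAnnotation,
    MissingTissueLabel,
    NotEnoughSamples,
    ZeroLibrarySize,
)

logger = logging.getLogger(__name__)

CPM_TOTAL = 1e6
UNKNOWN_LABEL = "UNKNOWN"


@dataclass
class CountsMatrix:
    """Non-negative counts, genes x samples (bulk) or genes x cells (UMI).

    ``values`` is a DataFrame indexed by gene symbol with one column per
    sample/cell. Gene and column ids must be unique and counts
    non-negative.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if (np.asarray(v.values) < 0).any():
            raise ValueError("counts matrix contains negative entries")
        if v.index.has_duplicates:
            raise ValueError("duplicate gene ids in counts matrix")
        if v.columns.has_duplicates:
            raise ValueError("duplicate column ids in counts matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def column_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CellAnnotation:
    """Per-cell annotation: cluster, inferred cell-type label, condition.

    ``table`` columns: cell_id, cluster_id, cell_type_label (text or
    ``UNKNOWN``), sample_condition (``normal`` | ``abnormal``),
    dataset_id. Every cell of the companion counts matrix must appear
    exactly once.
    """

    table: pd.DataFrame

    REQUIRED = ("cell_id", "cluster_id", "cell_type_label", "sample_condition", "dataset_id")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation table lacks columns: {missing}")
        if self.table["cell_id"].duplicated().any():
            raise ValueError("duplicate cell_id in annotation table")


@dataclass
class ExpressionPanel:
    """Gene x column expression in CPM with organ labels and provenance.

    ``kind`` is ``"tissue"`` for bulk-derived panels and ``"cell_type"``
    for single-cell pseudobulk panels. ``organ`` maps column id to a
    unified organ/tissue label; ``provenance`` holds free-form metadata
    per column (dataset, species, normalization notes).
    """

    values: pd.DataFrame
    kind: str = "tissue"
    organ: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, dict] = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def with_organ_map(self, organ_map: dict[str, str]) -> "ExpressionPanel":
        """Return a copy with organ labels joined from ``organ_map``."""
        organ = {c: organ_map[c] for c in self.columns if c in organ_map}
        return ExpressionPanel(self.values, self.kind, organ, dict(self.provenance))


def cpm_normalize(counts: pd.DataFrame | CountsMatrix) -> pd.DataFrame:
    """Scale each column to counts-per-million (column total 1e6).

    Proportions within a column are preserved; a zero-total column is a
    contract violation and raises :class:`ZeroLibrarySize` naming it.
    """
    df = counts.values if isinstance(counts, CountsMatrix) else counts
    totals = df.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ZeroLibrarySize(f"zero library size in column(s): {list(zero)}")
    return df * (CPM_TOTAL / totals)


def tmm_factors(
    counts: pd.DataFrame | CountsMatrix,
    reference_column: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, one per column.

    For each column k against the reference r, per-gene log ratios
    M_g = log2((x_gk/N_k) / (x_gr/N_r)) and average abundances
    A_g = 0.5 * log2(x_gk x_gr / (N_k N_r)) are computed over genes with
    positive counts in both columns. The most extreme ``trim_m`` of
    M-values (15% each tail) and ``trim_a`` of A-values (2.5% each tail)
    are discarded and the factor is 2**mean(M) over the survivors,
    rescaled so the factors have geometric mean 1. The reference column,
    if not given, is the one whose upper quartile (on CPM) is closest to
    the mean upper quartile across columns.

    A column differing from another only by sequencing depth yields a
    factor of 1: all its M-values vanish after library-size scaling.
    """
    df = counts.values if isinstance(counts, CountsMatrix) else counts
    if df.shape[1] < 2:
        raise NotEnoughSamples("TMM needs at least two columns")
    totals = df.sum(axis=0)
    if (totals <= 0).any():
        raise ZeroLibrarySize(
            f"zero library size in column(s): {list(totals.index[totals <= 0])}"
        )
    if reference_column is None:
        cpm = df * (CPM_TOTAL / totals)
        uq = cpm.quantile(0.75, axis=0)
        reference_column = (uq - uq.mean()).abs().idxmin()
    ref = df[reference_column].to_numpy(float)
    n_ref = ref.sum()

    factors = {}
    for col in df.columns:
        if col == reference_column:
            factors[col] = 1.0
            continue
        obs = df[col].to_numpy(float)
        keep = (obs > 0) & (ref > 0)
        o, r = obs[keep] / obs.sum(), ref[keep] / n_ref
        m = np.log2(o / r)
        a = 0.5 * np.log2(o * r)
        n = len(m)
        if n == 0:
            factors[col] = 1.0
            continue
        # rank-based double trim, as in the canonical TMM construction
        lo_m, hi_m = np.floor(n * trim_m / 2), n - np.floor(n * trim_m / 2)
        lo_a, hi_a = np.floor(n * trim_a / 2), n - np.floor(n * trim_a / 2)
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        kept = (rank_m > lo_m) & (rank_m <= hi_m) & (rank_a > lo_a) & (rank_a <= hi_a)
        factors[col] = float(2 ** np.mean(m[kept])) if kept.any() else 1.0

    f = pd.Series(factors).reindex(df.columns)
    f /= np.exp(np.mean(np.log(f)))  # geometric mean 1
    return f


def aggregate_bulk(
    panel_values: pd.DataFrame, sample_to_tissue: dict[str, str]
) -> ExpressionPanel:
    """Average CPM columns of samples belonging to the same tissue.

    Every sample column must be mapped; the per-tissue mean is
    re-normalized to CPM so each output column sums to 1e6 exactly.
    """
    unmapped = [c for c in panel_values.columns if c not in sample_to_tissue]
    if unmapped:
        raise MissingTissueLabel(f"samples without tissue label: {unmapped}")
    grouped = panel_values.T.groupby(
        panel_values.columns.map(sample_to_tissue)
    ).mean().T
    grouped = grouped[sorted(grouped.columns)]
    values = cpm_normalize(grouped)
    prov = {t: {"source": "bulk"} for t in values.columns}
    return ExpressionPanel(values, kind="tissue", provenance=prov)


def filter_cells(counts: CountsMatrix, min_umi: int = 300) -> CountsMatrix:
    """Drop cells whose total UMI count is below ``min_umi``.

    The boundary is strict: a cell with exactly ``min_umi`` UMIs is
    retained. An empty result is allowed and logged as a warning.
    """
    totals = counts.values.sum(axis=0)
    kept = counts.values.loc[:, totals >= min_umi]
    if kept.shape[1] == 0:
        logger.warning("filter_cells removed every cell (min_umi=%d)", min_umi)
    return CountsMatrix(kept)


def pseudobulk_clusters(
    counts: CountsMatrix,
    annotation: CellAnnotation,
    min_cells: int = 15,
    top_fraction: float = 0.10,
) -> ExpressionPanel:
    """Aggregate single-cell UMI counts into CPM cell-type profiles.

    Same-labeled clusters within one dataset are merged (cell pools are
    unioned before any selection). Pooled clusters are dropped when they
    have fewer than ``min_cells`` cells, carry the ``UNKNOWN`` label, or
    contain any cell from an abnormal (diseased) sample. Within each
    surviving pool, cells are ranked by total UMI and the top
    ``ceil(top_fraction * n_cells)`` are averaged on the raw count
    scale; the per-pool profile is then CPM-normalized.

    Column ids are the cell-type labels, suffixed with the dataset id
    when the same label occurs in several datasets.
    """
    ann = annotation.table.set_index("cell_id")
    cells = counts.column_ids
    missing = [c for c in cells if c not in ann.index]
    if missing:
        raise MissingAnnotation(f"cells without annotation: {missing[:5]}...")
    ann = ann.loc[cells]

    pools: dict[tuple[str, str], list[str]] = {}
    abnormal: set[tuple[str, str]] = set()
    for cell, row in ann.iterrows():
        key = (str(row["dataset_id"]), str(row["cell_type_label"]))
        pools.setdefault(key, []).append(cell)
        if str(row["sample_condition"]) != "normal":
            abnormal.add(key)

    profiles: dict[tuple[str, str], np.ndarray] = {}
    for key, pool in sorted(pools.items()):
        dataset, label = key
        if label == UNKNOWN_LABEL:
            logger.info("dropping unlabeled pool in dataset %s", dataset)
            continue
        if key in abnormal:
            logger.info("dropping abnormal pool %s in dataset %s", label, dataset)
            continue
        if len(pool) < min_cells:
            logger.info(
                "dropping pool %s (%d cells < %d)", label, len(pool), min_cells
            )
            continue
        sub = counts.values[pool]
        n_top = math.ceil(top_fraction * len(pool))
        order = sub.sum(axis=0).sort_values(ascending=False, kind="stable")
        top_cells = list(order.index[:n_top])
        profiles[key] = sub[top_cells].mean(axis=1).to_numpy()

    if not profiles:
        logger.warning("pseudobulk_clusters produced no surviving cell types")
        return ExpressionPanel(
            pd.DataFrame(index=counts.values.index), kind="cell_type"
        )

    labels = [label for (_, label) in profiles]
    dup = {l for l in labels if labels.count(l) > 1}
    columns, data, prov = [], [], {}
    for (dataset, label), prof in profiles.items():
        name = f"{label} ({dataset})" if label in dup else label
        columns.append(name)
        data.append(prof)
        prov[name] = {"source": "single-cell pseudobulk", "dataset": dataset}
    values = pd.DataFrame(
        np.column_stack(data), index=counts.values.index, columns=columns
    )
    return ExpressionPanel(cpm_normalize(values), kind="cell_type", provenance=prov)


def map_homologs(panel: ExpressionPanel, mapping: pd.DataFrame) -> ExpressionPanel:
    """Rename genes to human HGNC symbols via a two-column mapping table.

    ``mapping`` columns: ``source`` (species gene id) and ``target``
    (HGNC symbol). Only strictly one-to-one pairs survive: genes with no
    mapping row, sources mapping to several symbols, and several sources
    sharing one symbol are all dropped (counts logged). Expression
    values are kept as-is — column totals may fall below 1e6 after gene
    removal, which is recorded in provenance rather than re-normalized
    away.
    """
    mapping = mapping.drop_duplicates()
    src_counts = mapping["source"].value_counts()
    tgt_counts = mapping["target"].value_counts()
    one_to_one = mapping[
        mapping["source"].map(src_counts).eq(1) & mapping["target"].map(tgt_counts).eq(1)
    ]
    lut = dict(zip(one_to_one["source"], one_to_one["target"]))
    keep = [g for g in panel.genes if g in lut]
    n_dropped = len(panel.genes) - len(keep)
    if n_dropped:
        logger.info("map_homologs dropped %d genes without 1:1 HGNC mapping", n_dropped)
    values = panel.values.loc[keep].rename(index=lut)
    prov = {
        c: {**panel.provenance.get(c, {}), "homolog_mapped": True, "renormalized": False}
        for c in values.columns
    }
    return ExpressionPanel(values, kind=panel.kind, organ=dict(panel.organ), provenance=prov)
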