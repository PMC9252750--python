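"""Synthetic fixtures: LD-structured genotypes, driver-tissue panels,
single-cell counts and GWAS summary statistics with planted causal genes.

Every stage of the pipeline can be exercised without downloading any
reference resource. The generator plants a known truth — a driver
tissue/cell type whose selectively expressed genes carry the GWAS
signal — so parameter-recovery tests have an exact answer:

* genotypes: one independent LD block per gene, drawn by thresholding a
  latent Gaussian with AR(1) correlation ``rho`` at the configured
  allele frequency (default 0.3), two haplotypes per sample;
* expression: log-normal baseline across tissues with an additive
  log2-scale boost (default +2) for causal genes in the driver column
  only;
* GWAS: null variants receive Uniform(0,1) P-values, causal-gene
  variants P-values from a noncentral 1-df chi-square (association is
  injected at the P-value level, which is all the downstream method
  consumes);
* single-cell counts: Poisson draws at per-cluster depths, with
  designed sub-threshold cells, small clusters, unlabeled clusters,
  diseased samples and duplicate labels so every panel-construction
  rule fires.

All generators are deterministic in ``config.seed`` and return a
manifest echoing the configuration and truth (driver id, causal genes,
expected surviving cell types).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .gwas import GeneRegion, ReferencePanel
from .panel import CellAnnotation, CountsMatrix, ExpressionPanel, cpm_normalize

P_FLOOR = 1e-300
N_CHROM = 22


@dataclass
class ClusterSpec:
    """One designed single-cell cluster."""

    cluster_id: str
    n_cells: int
    label: str
    condition: str = "normal"
    depth: float = 2000.0
    dataset: str = "ds1"


def default_sc_cluster_spec() -> list[ClusterSpec]:
    """Clusters exercising every pseudobulk filtering rule.

    Survivors by design: A (plain), B (two same-labeled clusters merged,
    one of them individually below the 15-cell floor). Dropped: C
    (< 15 cells), D (UNKNOWN label), E (abnormal sample), F (all cells
    below the 300-UMI floor).
    """
    return [
        ClusterSpec("c_a", 30, "A"),
        ClusterSpec("c_b1", 20, "B"),
        ClusterSpec("c_b2", 10, "B"),
        ClusterSpec("c_c", 14, "C"),
        ClusterSpec("c_d", 20, "UNKNOWN"),
        ClusterSpec("c_e", 20, "E", condition="abnormal"),
        ClusterSpec("c_f", 20, "F", depth=10.0),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic fixtures."""

    seed: int = 1
    n_tissues: int = 20
    n_genes: int = 1000
    n_causal: int = 40
    driver_index: int = 5            # 1-based tissue index of the planted driver
    block_size: int = 5              # variants per gene LD block
    rho: float = 0.5                 # AR(1) latent correlation within a block
    n_samples: int = 500             # reference-panel diploid samples
    allele_freq: float = 0.3
    noncentrality: float = 30.0      # per causal variant, 1-df chi-square
    boost: float = 2.0               # log2 expression boost in the driver
    celltypes_per_organ: int = 3
    n_sc_genes: int = 50
    sc_cluster_spec: list[ClusterSpec] = field(default_factory=default_sc_cluster_spec)

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if self.n_causal > self.n_genes:
            raise ValueError("n_causal exceeds n_genes")
        if self.noncentrality < 0:
            raise ValueError("noncentrality must be >= 0")

    @property
    def driver(self) -> str:
        return f"T{self.driver_index:02d}"

    @property
    def driver_celltype(self) -> str:
        return f"CT_{self.driver_index:02d}_1"

    def gene_symbols(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def causal_genes(config: SimulationConfig) -> list[str]:
    """The planted causal gene set (deterministic in the seed)."""
    rng = _rng(config, 7)
    idx = np.sort(rng.choice(config.n_genes, size=config.n_causal, replace=False))
    symbols = config.gene_symbols()
    return [symbols[i] for i in idx]


def gene_regions(config: SimulationConfig, flank: int = 5_000) -> list[GeneRegion]:
    """One gene window per LD block, spread over 22 chromosomes.

    Genes on one chromosome are spaced 500 kb apart with 100 bp between
    block variants, so neighboring windows never overlap at the default
    flank while same-chromosome genes still fall inside the 10 Mb
    conditioning window.
    """
    regions = []
    for i, symbol in enumerate(config.gene_symbols()):
        chrom = str(i % N_CHROM + 1)
        base = 1_000_000 + (i // N_CHROM) * 500_000
        end = base + (config.block_size - 1) * 100
        regions.append(GeneRegion(symbol, chrom, base, end, flank))
    return regions


def _ar1_cholesky(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    cov = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(cov)


def simulate_genotypes(config: SimulationConfig) -> tuple[ReferencePanel, list[GeneRegion]]:
    """Reference-panel dosages with block-AR(1) LD, plus gene windows."""
    rng = _rng(config, 11)
    regions = gene_regions(config)
    bs, n = config.block_size, config.n_samples
    chol = _ar1_cholesky(bs, config.rho)
    thresh = norm.isf(config.allele_freq)

    eps = rng.standard_normal((config.n_genes, 2 * n, bs))
    latent = eps @ chol.T
    alleles = (latent > thresh).astype(np.int8)
    dosage = alleles[:, 0::2, :] + alleles[:, 1::2, :]  # genes x samples x block

    ids, chroms, poss, rows = [], [], [], []
    for i, region in enumerate(regions):
        for v in range(bs):
            pos = region.start + v * 100
            ids.append(f"{region.chromosome}:{pos}")
            chroms.append(region.chromosome)
            poss.append(pos)
            rows.append(dosage[i, :, v])
    panel = ReferencePanel(
        ids=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        dosages=np.array(rows, dtype=float),
    )
    return panel, regions


def write_vcf(panel: ReferencePanel, path: str | Path) -> None:
    """Write the panel as a minimal sorted VCF 4.2 with GT fields."""
    n = panel.n_samples
    samples = [f"S{i + 1:04d}" for i in range(n)]
    order = sorted(
        range(panel.n_variants),
        key=lambda i: (int(panel.chrom[i]) if str(panel.chrom[i]).isdigit() else 99,
                       str(panel.chrom[i]), int(panel.pos[i])),
    )
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dese-simulate\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(str(panel.chrom[i]) for i in order):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i in order:
            gts = "\t".join(gt_code[int(round(d))] for d in panel.dosages[i])
            fh.write(f"{panel.chrom[i]}\t{panel.pos[i]}\t{panel.ids[i]}\t"
                     f"A\tG\t.\tPASS\t.\tGT\t{gts}\n")


def simulate_panel_vcf(
    config: SimulationConfig, out_path: str | Path | None = None
) -> tuple[ReferencePanel, list[GeneRegion], dict]:
    """Genotype panel plus gene windows; optionally written as VCF."""
    panel, regions = simulate_genotypes(config)
    if out_path is not None:
        write_vcf(panel, out_path)
    manifest = {
        "n_variants": panel.n_variants,
        "n_samples": panel.n_samples,
        "rho": config.rho,
        "block_size": config.block_size,
    }
    return panel, regions, manifest


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionPanel, list[str]]:
    """Bulk tissue panel with causal genes boosted in the driver column."""
    rng = _rng(config, 23)
    symbols = config.gene_symbols()
    causal = causal_genes(config)
    cols = [f"T{t + 1:02d}" for t in range(config.n_tissues)]
    mu = rng.normal(5.0, 2.0, size=config.n_genes)
    log_expr = mu[:, None] + rng.normal(0.0, 1.0, size=(config.n_genes, len(cols)))
    causal_idx = [symbols.index(g) for g in causal]
    log_expr[causal_idx, config.driver_index - 1] += config.boost
    values = pd.DataFrame(2.0 ** log_expr, index=symbols, columns=cols)
    organ = {c: f"O{t + 1:02d}" for t, c in enumerate(cols)}
    panel = ExpressionPanel(cpm_normalize(values), kind="tissue", organ=organ,
                            provenance={c: {"source": "synthetic bulk"} for c in cols})
    return panel, causal


def simulate_celltype_panel(config: SimulationConfig) -> tuple[ExpressionPanel, list[str]]:
    """Cell-type panel sharing the organ vocabulary of the tissue panel.

    Each organ contributes ``celltypes_per_organ`` columns; the first
    cell type of the driver's organ carries the causal boost, so the
    hierarchical stage has a recoverable cell-type truth.
    """
    rng = _rng(config, 29)
    symbols = config.gene_symbols()
    causal = causal_genes(config)
    cols, organ = [], {}
    for t in range(config.n_tissues):
        for j in range(config.celltypes_per_organ):
            name = f"CT_{t + 1:02d}_{j + 1}"
            cols.append(name)
            organ[name] = f"O{t + 1:02d}"
    mu = rng.normal(5.0, 2.0, size=config.n_genes)
    log_expr = mu[:, None] + rng.normal(0.0, 1.0, size=(config.n_genes, len(cols)))
    causal_idx = [symbols.index(g) for g in causal]
    log_expr[causal_idx, cols.index(config.driver_celltype)] += config.boost
    values = pd.DataFrame(2.0 ** log_expr, index=symbols, columns=cols)
    panel = ExpressionPanel(
        cpm_normalize(values), kind="cell_type", organ=organ,
        provenance={c: {"source": "synthetic pseudobulk"} for c in cols},
    )
    return panel, causal


def simulate_gwas(
    config: SimulationConfig,
    regions: list[GeneRegion],
    causal: list[str],
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """GWAS summary statistics with signal planted in causal genes.

    Null variants draw P ~ Uniform(0,1); each variant of a causal gene
    draws its chi-square from a noncentral 1-df chi-square at the
    configured noncentrality and converts it to a P-value.
    """
    rng = _rng(config, 31)
    causal_set = set(causal)
    chroms, poss, ps = [], [], []
    for region in regions:
        bs = config.block_size
        if region.symbol in causal_set and config.noncentrality > 0:
            q = rng.noncentral_chisquare(1.0, config.noncentrality, size=bs)
            p = chi2.sf(q, 1)
        else:
            p = rng.uniform(size=bs)
        p = np.clip(p, P_FLOOR, 1.0)
        for v in range(bs):
            chroms.append(region.chromosome)
            poss.append(region.start + v * 100)
            ps.append(float(p[v]))
    df = pd.DataFrame({"chrom": chroms, "pos": poss, "p": ps})
    if out_path is not None:
        from .gwas import write_summary

        write_summary(df, out_path)
    return df


def simulate_sc_counts(
    config: SimulationConfig, min_umi: int = 300
) -> tuple[CountsMatrix, CellAnnotation, dict]:
    """Designed single-cell UMI counts, annotations and expected truth.

    Counts are Poisson at each cluster's configured mean depth over a
    shared gene-weight profile. The manifest records the cell-type
    columns that must survive panel construction: pooled same-labeled
    clusters of adequately sequenced cells (depth comfortably above the
    UMI floor), with at least 15 cells, a known label and normal
    condition.
    """
    rng = _rng(config, 37)
    genes = [f"SG{i + 1:03d}" for i in range(config.n_sc_genes)]
    weights = rng.dirichlet(np.ones(config.n_sc_genes))

    cell_ids, rows = [], []
    ann_rows = []
    for spec in config.sc_cluster_spec:
        lam = spec.depth * weights
        for c in range(spec.n_cells):
            cid = f"{spec.cluster_id}_{c + 1:03d}"
            cell_ids.append(cid)
            rows.append(rng.poisson(lam))
            ann_rows.append(
                (cid, spec.cluster_id, spec.label, spec.condition, spec.dataset)
            )
    counts = CountsMatrix(
        pd.DataFrame(np.array(rows).T, index=genes, columns=cell_ids)
    )
    annotation = CellAnnotation(
        pd.DataFrame(
            ann_rows,
            columns=["cell_id", "cluster_id", "cell_type_label",
                     "sample_condition", "dataset_id"],
        )
    )

    pools: dict[tuple[str, str], int] = {}
    bad: set[tuple[str, str]] = set()
    for spec in config.sc_cluster_spec:
        key = (spec.dataset, spec.label)
        survives_umi = spec.depth >= 2 * min_umi
        pools[key] = pools.get(key, 0) + (spec.n_cells if survives_umi else 0)
        if spec.condition != "normal" or spec.label == "UNKNOWN":
            bad.add(key)
    expected = sorted(
        label for (ds, label), n in pools.items()
        if n >= 15 and (ds, label) not in bad
    )
    manifest = {
        "expected_columns": expected,
        "min_umi": min_umi,
        "clusters": [asdict(s) for s in config.sc_cluster_spec],
    }
    return counts, annotation, manifest
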