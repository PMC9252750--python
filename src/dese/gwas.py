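"""GWAS summary-statistic ingestion, reference genotypes and LD.

The gene-based association step consumes per-variant P-values from a
headered tab- or comma-delimited summary file (chromosome, base-pair
position, P-value at minimum) together with genotype dosages from an
ancestrally matched reference VCF, from which pairwise linkage
disequilibrium (Pearson r of dosages) is estimated. The summary file
must contain the full variant set — pre-filtering on significance
inflates the gene-based test.

Coordinates are 1-based inclusive throughout; BED gene annotations
(0-based half-open) are converted on read. Chromosome labels are
normalized by stripping a leading ``chr``.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, MissingVariant, RowError

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


@dataclass(frozen=True)
class VariantAssociation:
    """One GWAS variant: chromosome label, 1-based position, P-value."""

    chromosome: str
    position: int
    pvalue: float


@dataclass(frozen=True)
class GeneRegion:
    """A gene window on a chromosome, 1-based inclusive, plus flank."""

    symbol: str
    chromosome: str
    start: int
    end: int
    flank: int = 5_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.symbol}: start > end")
        if self.flank < 0:
            raise ValueError(f"{self.symbol}: negative flank")


@dataclass
class ReferencePanel:
    """Genotype dosages (variants x samples) for LD estimation.

    ``dosages`` holds additively coded genotypes (0/1/2, missing calls
    imputed to the per-site mean); ``chrom``/``pos`` are parallel
    per-variant arrays and ``ids`` the variant identifiers.
    """

    ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.ids)}

    @property
    def n_variants(self) -> int:
        return len(self.ids)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def rows(self, variant_ids: Iterable[str]) -> np.ndarray:
        idx = []
        for v in variant_ids:
            if v not in self._index:
                raise MissingVariant(f"variant {v!r} absent from reference panel")
            idx.append(self._index[v])
        return np.asarray(idx, dtype=int)


@dataclass
class LDMatrix:
    """Pairwise Pearson correlations of dosages for a variant set."""

    ids: list[str]
    r: np.ndarray


def normalize_chrom(label: str) -> str:
    label = str(label).strip()
    return label[3:] if label.lower().startswith("chr") else label


def _resolve_columns(header: list[str], column_map: Mapping[str, str] | None) -> dict[str, str]:
    wanted = {"chrom": ["chr", "chrom", "chromosome"],
              "pos": ["bp", "pos", "position", "bp_pos"],
              "p": ["p", "pvalue", "p_value", "pval"]}
    if column_map:
        resolved = {}
        for key in ("chrom", "pos", "p"):
            name = column_map.get(key)
            if name is None or name not in header:
                raise FormatError(f"required column for {key!r} not found in header")
            resolved[key] = name
        return resolved
    lower = {h.lower(): h for h in header}
    resolved = {}
    for key, aliases in wanted.items():
        hit = next((lower[a] for a in aliases if a in lower), None)
        if hit is None:
            raise FormatError(
                f"no column for {key!r} in header {header}; use column_map"
            )
        resolved[key] = hit
    return resolved


def read_summary(
    path: str | Path | io.StringIO,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Parse a GWAS summary file into a chrom/pos/p DataFrame.

    The delimiter (tab vs comma) is sniffed from the header line; extra
    columns are ignored and no P-value filtering is applied. P = 0 is
    clamped to 1e-300 with a warning; P outside (0, 1] otherwise, or
    non-numeric fields, raise :class:`RowError` with the line number.
    """
    if isinstance(path, io.StringIO):
        text = path.getvalue()
    else:
        text = Path(path).read_text()
    lines = text.splitlines()
    if not lines:
        raise FormatError("empty summary file")
    delim = "\t" if "\t" in lines[0] else ","
    header = [h.strip() for h in lines[0].split(delim)]
    if any(_is_number(h) for h in header):
        raise FormatError("summary file must start with a header line")
    cols = _resolve_columns(header, column_map)
    ic, ip_, ipv = (header.index(cols[k]) for k in ("chrom", "pos", "p"))

    chroms, poss, ps = [], [], []
    n_clamped = 0
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(delim)
        try:
            pos = int(float(fields[ip_]))
            p = float(fields[ipv])
        except (ValueError, IndexError) as exc:
            raise RowError(f"line {lineno}: non-numeric position or P-value") from exc
        if pos <= 0:
            raise RowError(f"line {lineno}: non-positive position {pos}")
        if p == 0.0:
            p = P_FLOOR
            n_clamped += 1
        elif not (0.0 < p <= 1.0):
            raise RowError(f"line {lineno}: P-value {p} outside (0, 1]")
        chroms.append(normalize_chrom(fields[ic]))
        poss.append(pos)
        ps.append(p)
    if n_clamped:
        warnings.warn(f"{n_clamped} zero P-value(s) clamped to {P_FLOOR}")
    return pd.DataFrame({"chrom": chroms, "pos": poss, "p": ps})


def write_summary(variants: pd.DataFrame, path: str | Path, delim: str = "\t") -> None:
    """Write a chrom/pos/p DataFrame as a headered summary file."""
    out = variants.rename(columns={"chrom": "CHR", "pos": "BP", "p": "P"})
    out.to_csv(path, sep=delim, index=False)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def load_panel(vcf_path: str | Path, region: str | None = None) -> ReferencePanel:
    """Load biallelic-SNV dosages from a VCF reference panel.

    Missing genotypes are imputed to the per-site mean dosage;
    monomorphic sites and non-SNV/multiallelic records are skipped with
    a logged count.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise FormatError(f"unreadable VCF {vcf_path}: {exc}") from exc

    ids, chroms, poss, rows = [], [], [], []
    n_skipped = n_mono = 0
    iterator = vcf(region) if region else vcf
    for v in iterator:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = np.array([g[:2] for g in v.genotypes], dtype=float)
        gts[gts < 0] = np.nan
        dose = gts.sum(axis=1)
        if np.isnan(dose).any():
            dose = np.where(np.isnan(dose), np.nanmean(dose), dose)
        if np.nanstd(dose) == 0 or np.isnan(dose).all():
            n_mono += 1
            continue
        vid = v.ID if v.ID not in (None, ".") else f"{normalize_chrom(v.CHROM)}:{v.POS}"
        ids.append(vid)
        chroms.append(normalize_chrom(v.CHROM))
        poss.append(v.POS)
        rows.append(dose)
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNV records", n_skipped)
    if n_mono:
        logger.warning("excluded %d monomorphic site(s)", n_mono)
    if not rows:
        raise FormatError(f"no usable variants in {vcf_path}")
    return ReferencePanel(
        ids=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        dosages=np.vstack(rows),
    )


def read_gene_regions(path: str | Path, flank: int = 5_000) -> list[GeneRegion]:
    """Read gene windows from BED (0-based half-open) or headered TSV.

    A file whose first line is a header (``symbol  chrom  start  end``)
    is treated as 1-based inclusive; a headerless 4+ column file is
    treated as BED with the symbol in column 4.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError("empty gene annotation file")
    first = lines[0].split("\t")
    regions: list[GeneRegion] = []
    if not _is_number(first[1]) and not _is_number(first[2]):
        for line in lines[1:]:
            if not line.strip():
                continue
            sym, chrom, start, end = line.split("\t")[:4]
            regions.append(
                GeneRegion(sym, normalize_chrom(chrom), int(start), int(end), flank)
            )
    else:
        for line in lines:
            if not line.strip():
                continue
            chrom, start, end, sym = line.split("\t")[:4]
            regions.append(
                GeneRegion(sym, normalize_chrom(chrom), int(start) + 1, int(end), flank)
            )
    return regions


def map_variants_to_genes(
    variants: pd.DataFrame, genes: list[GeneRegion]
) -> tuple[dict[str, np.ndarray], int]:
    """Assign variants to gene windows (start-flank .. end+flank, inclusive).

    Returns a mapping symbol -> array of row indices into ``variants``
    (a variant may fall in several overlapping windows) and the count of
    variants assigned to no gene.
    """
    variants = variants.reset_index(drop=True)
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): sub for c, sub in variants.groupby("chrom")
    }
    assignment: dict[str, np.ndarray] = {}
    assigned = np.zeros(len(variants), dtype=bool)
    for gene in genes:
        sub = by_chrom.get(gene.chromosome)
        if sub is None:
            assignment[gene.symbol] = np.array([], dtype=int)
            continue
        lo, hi = gene.start - gene.flank, gene.end + gene.flank
        mask = (sub["pos"].to_numpy() >= lo) & (sub["pos"].to_numpy() <= hi)
        idx = sub.index.to_numpy()[mask]
        assignment[gene.symbol] = idx
        assigned[idx] = True
    return assignment, int((~assigned).sum())


def ld_matrix(panel: ReferencePanel, variant_ids: Iterable[str]) -> LDMatrix:
    """Pearson correlation of dosage vectors for the requested variants."""
    variant_ids = list(variant_ids)
    rows = panel.rows(variant_ids)
    x = panel.dosages[rows]
    if len(rows) == 1:
        return LDMatrix(variant_ids, np.ones((1, 1)))
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(variant_ids, np.clip(r, -1.0, 1.0))
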