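"""Text-format readers and writers.

Dense counts and panels travel as headered TSV (first column = gene
symbol); sparse single-cell counts as MatrixMarket triplets with gene
and barcode sidecar files; annotations and mapping tables as headered
TSV. Paths ending in ``.gz`` are gzip-compressed with a zeroed
timestamp so identical runs produce byte-identical files.
"""

from __future__ import annotations

import gzip
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .panel import CellAnnotation, CountsMatrix, ExpressionPanel


def _open_text_write(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        raw = open(path, "wb")
        gz = gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
        return _io.TextIOWrapper(gz, encoding="utf-8", newline="")
    return open(path, "w", encoding="utf-8", newline="")


def _open_text_read(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return _io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, encoding="utf-8")


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    with _open_text_write(path) as fh:
        df.to_csv(fh, sep="\t", index_label=index_label, lineterminator="\n")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    with _open_text_read(path) as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


def write_panel(panel: ExpressionPanel, path: str | Path) -> None:
    write_matrix_tsv(panel.values, path)


def read_panel(
    path: str | Path, kind: str = "tissue", organ_map: dict[str, str] | None = None
) -> ExpressionPanel:
    values = read_matrix_tsv(path)
    panel = ExpressionPanel(values, kind=kind)
    return panel.with_organ_map(organ_map) if organ_map else panel


def read_counts_tsv(path: str | Path) -> CountsMatrix:
    return CountsMatrix(read_matrix_tsv(path))


def read_counts_mtx(
    mtx_path: str | Path, genes_path: str | Path, barcodes_path: str | Path
) -> CountsMatrix:
    """Read MatrixMarket triplet counts with gene/barcode sidecars."""
    from scipy.io import mmread

    mat = mmread(str(mtx_path)).toarray()
    genes = Path(genes_path).read_text().split()
    barcodes = Path(barcodes_path).read_text().split()
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"MTX shape {mat.shape} does not match {len(genes)} genes x "
            f"{len(barcodes)} barcodes"
        )
    return CountsMatrix(pd.DataFrame(mat, index=genes, columns=barcodes))


def read_cell_annotations(path: str | Path) -> CellAnnotation:
    with _open_text_read(path) as fh:
        return CellAnnotation(pd.read_csv(fh, sep="\t", dtype=str))


def write_cell_annotations(ann: CellAnnotation, path: str | Path) -> None:
    with _open_text_write(path) as fh:
        ann.table.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_two_column_map(path: str | Path, key: str, value: str) -> dict[str, str]:
    with _open_text_read(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    for col in (key, value):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return dict(zip(df[key], df[value]))


def read_organ_map(path: str | Path) -> dict[str, str]:
    """Headered TSV mapping panel column ids to unified organ labels."""
    return read_two_column_map(path, "column_id", "organ")


def read_homolog_map(path: str | Path) -> pd.DataFrame:
    """Headered TSV with ``source`` (species gene) and ``target`` (HGNC)."""
    with _open_text_read(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    if not {"source", "target"} <= set(df.columns):
        raise FormatError(f"{path}: homolog map needs 'source' and 'target' columns")
    return df


def write_json(obj, path: str | Path) -> None:
    with _open_text_write(path) as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
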