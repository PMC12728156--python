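"""Readers and writers for the package's file formats, plus small
cohort-arithmetic helpers.

Formats: TSV expression matrices (gene rows, sample columns), GMT gene
sets, TSV clone tables (sample/clonotype/count), CSV spatial tables,
MTX-triplet single-cell directories with a ``labels.tsv`` sidecar, TSV gene
position tables, CSV sample metadata.
"""
from __future__ import annotations

import logging
import math
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import DomainError, FormatError
from .types import (
    CELL_TYPES,
    CloneTable,
    ExpressionMatrix,
    GenePositionTable,
    GeneSet,
    REQUIRED_SPATIAL_PANEL,
    SampleMetadata,
    SpatialCellTable,
    metadata_to_frame,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# expression matrices

def read_expression(path: PathLike, scale: str = "raw") -> ExpressionMatrix:
    """Read a tab-delimited genes x samples matrix (first column gene ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse expression file {path}: {exc}") from exc
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    dup_genes = df.index[df.index.duplicated()]
    if len(dup_genes):
        raise FormatError(f"duplicate gene identifier: {dup_genes[0]!r}")
    dup_samples = df.columns[df.columns.duplicated()]
    if len(dup_samples):
        raise FormatError(f"duplicate sample identifier: {dup_samples[0]!r}")
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = df.index[(bad | df[col].isna())][0]
            raise FormatError(
                f"non-numeric or missing value at gene {row!r}, sample {col!r}"
            )
        df[col] = vals.astype(float)
    return ExpressionMatrix(df, scale=scale)


def write_expression(matrix: ExpressionMatrix, path: PathLike) -> None:
    """Write a matrix as TSV with 6-decimal precision (round-trip safe)."""
    matrix.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path: PathLike) -> list[GeneSet]:
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, description, genes")
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if not genes:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
        sets.append(GeneSet(name=name, description=desc, genes=genes))
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return sets


def write_gmt(sets: Sequence[GeneSet], path: PathLike) -> None:
    lines = ["\t".join([s.name, s.description or "na", *s.genes]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


def default_mcp_populations() -> list[GeneSet]:
    """Bundled marker-gene sets for microenvironment cell populations.

    A compact, editable marker file in the spirit of MCP-counter; callers
    may substitute their own GMT.
    """
    with resources.as_file(
        resources.files("pdoimmune.data") / "mcp_populations.gmt"
    ) as p:
        return read_gmt(p)


# ---------------------------------------------------------------------------
# clone tables

def read_clone_table(path: PathLike) -> CloneTable:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample", "clonotype", "count"} - set(df.columns)
    if missing:
        raise FormatError(f"clone table {path} missing columns: {sorted(missing)}")
    return CloneTable(df[["sample", "clonotype", "count"]].copy())


def write_clone_table(table: CloneTable, path: PathLike) -> None:
    table.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# spatial tables

def read_spatial(path: PathLike, panel: Optional[Sequence[str]] = None) -> SpatialCellTable:
    df = pd.read_csv(path)
    panel_t = tuple(panel) if panel is not None else REQUIRED_SPATIAL_PANEL
    return SpatialCellTable(df, panel=panel_t)


def write_spatial(table: SpatialCellTable, path: PathLike) -> None:
    table.cells.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# labeled single-cell matrices (MTX triplet + labels sidecar)

def validate_labeled_cells(adata: ad.AnnData) -> ad.AnnData:
    """Enforce LabeledCellMatrix invariants on an AnnData (cells x genes)."""
    if "cell_type" not in adata.obs.columns:
        raise FormatError("cell matrix needs an obs['cell_type'] column")
    bad = set(map(str, adata.obs["cell_type"].unique())) - set(CELL_TYPES)
    if bad:
        raise FormatError(f"unknown cell types: {sorted(bad)}")
    if adata.obs_names.duplicated().any():
        raise FormatError("duplicate cell identifiers")
    if adata.var_names.duplicated().any():
        raise FormatError("duplicate gene identifiers")
    x = adata.X
    data = x.data if scipy.sparse.issparse(x) else np.asarray(x)
    if (data < 0).any():
        raise FormatError("cell counts must be non-negative")
    if not np.allclose(data, np.round(data)):
        raise FormatError("cell counts must be integral")
    return adata


def read_cell_matrix(mtx_dir: PathLike) -> ad.AnnData:
    """Read matrix.mtx + features.tsv + barcodes.tsv + labels.tsv.

    matrix.mtx is genes x cells (CellRanger convention); the returned
    AnnData is cells x genes. labels.tsv has columns barcode, cell_type
    and optionally origin.
    """
    d = Path(mtx_dir)
    for fname in ("matrix.mtx", "features.tsv", "barcodes.tsv", "labels.tsv"):
        if not (d / fname).exists():
            raise FormatError(f"missing {fname} in {d}")
    mat = scipy.io.mmread(d / "matrix.mtx").tocsr().T  # -> cells x genes
    genes = pd.read_csv(d / "features.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    labels = pd.read_csv(d / "labels.tsv", sep="\t")
    if "barcode" not in labels.columns or "cell_type" not in labels.columns:
        raise FormatError("labels.tsv needs columns barcode, cell_type")
    labels = labels.set_index("barcode")
    missing = [b for b in barcodes if b not in labels.index]
    if missing:
        raise FormatError(f"barcodes without a cell label: {missing[:3]}")
    obs = labels.loc[barcodes, ["cell_type"]].copy()
    if "origin" in labels.columns:
        obs["origin"] = labels.loc[barcodes, "origin"].values
    obs.index = pd.Index(barcodes, name="barcode")
    adata = ad.AnnData(X=mat.astype(np.int64), obs=obs,
                       var=pd.DataFrame(index=pd.Index(genes, name="gene_id")))
    return validate_labeled_cells(adata)


def write_cell_matrix(adata: ad.AnnData, mtx_dir: PathLike) -> None:
    d = Path(mtx_dir)
    d.mkdir(parents=True, exist_ok=True)
    x = adata.X
    if not scipy.sparse.issparse(x):
        x = scipy.sparse.csr_matrix(x)
    scipy.io.mmwrite(str(d / "matrix.mtx"), x.T.astype(np.int64))
    pd.Series(adata.var_names).to_csv(d / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(d / "barcodes.tsv", sep="\t", index=False, header=False)
    labels = pd.DataFrame({"barcode": adata.obs_names,
                           "cell_type": adata.obs["cell_type"].values})
    if "origin" in adata.obs.columns:
        labels["origin"] = adata.obs["origin"].values
    labels.to_csv(d / "labels.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene positions and sample metadata

def read_positions(path: PathLike) -> GenePositionTable:
    df = pd.read_csv(path, sep="\t")
    return GenePositionTable(df)


def write_positions(table: GenePositionTable, path: PathLike) -> None:
    table.positions.to_csv(path, sep="\t", index=False)


_META_COLS = ["sample_id", "patient_id", "tissue", "culture_type", "timepoint",
              "response", "survival_time", "survival_event"]


def read_metadata(path: PathLike) -> list[SampleMetadata]:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "patient_id" not in df.columns:
        raise FormatError("metadata needs sample_id and patient_id columns")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in _META_COLS:
            if col in df.columns and pd.notna(row[col]):
                kwargs[col] = row[col]
        if "survival_time" in kwargs:
            kwargs["survival_time"] = float(kwargs["survival_time"])
        if "survival_event" in kwargs:
            kwargs["survival_event"] = int(kwargs["survival_event"])
        records.append(SampleMetadata(**kwargs))
    metadata_to_frame(records)  # validates uniqueness
    return records


def write_metadata(records: Sequence[SampleMetadata], path: PathLike) -> None:
    metadata_to_frame(records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cohort arithmetic

def percent(numerator: int, denominator: int) -> int:
    """Integer percentage, rounding half away from zero.

    percent(22, 31) == 71; percent(11, 14) == 79 — matching clinical-table
    conventions where .5 rounds up.
    """
    if denominator == 0:
        raise DomainError("percent: denominator must be > 0")
    if denominator < 0 or numerator < 0 or numerator > denominator:
        raise DomainError("percent: need 0 <= numerator <= denominator, denominator > 0")
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5))


_CATEGORICAL_FIELDS = ["tissue", "culture_type", "timepoint", "response"]


def cohort_summary(
    metadata: Union[Sequence[SampleMetadata], pd.DataFrame],
    columns: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Category counts and percentages per clinical feature.

    Accepts either SampleMetadata records (summarising the categorical
    fields) or a DataFrame of clinical features (one row per patient, one
    column per feature). Returns columns feature, category, n, percent.
    """
    if isinstance(metadata, pd.DataFrame):
        df = metadata
        cols = list(columns) if columns is not None else list(df.columns)
    else:
        if len(metadata) == 0:
            raise DomainError("cohort_summary: empty metadata")
        df = metadata_to_frame(metadata)
        cols = list(columns) if columns is not None else _CATEGORICAL_FIELDS
    if len(df) == 0:
        raise DomainError("cohort_summary: empty cohort")
    total = len(df)
    rows = []
    for col in cols:
        counts = df[col].value_counts(dropna=False)
        for category, n in counts.items():
            rows.append({
                "feature": col,
                "category": category,
                "n": int(n),
                "percent": percent(int(n), total),
            })
    out = pd.DataFrame(rows, columns=["feature", "category", "n", "percent"])
    assert out.groupby("feature")["n"].sum().eq(total).all()
    return out
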