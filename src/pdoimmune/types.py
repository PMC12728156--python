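"""Domain types for PDO immuno-transcriptomic analysis.

All tabular containers wrap pandas objects and validate their invariants on
construction, so every downstream stage can assume well-formed inputs.
Expression is stored genes x samples; single-cell data uses an AnnData
(cells x genes) with ``obs['cell_type']`` and ``obs['origin']``.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError

TISSUES = ("metastasis", "pdo")
CULTURE_TYPES = ("semi_solid", "ali", "none")
TIMEPOINTS = ("baseline", "stimulated", "pre_treatment", "on_treatment", "none")
RESPONSES = ("responder", "non_responder", "unknown")

CELL_TYPES = (
    "T_cell",
    "CD8_T",
    "B_cell",
    "myeloid",
    "melanoma",
    "fibroblast",
    "endothelial",
    "other",
)

#: immune labels used for proximity analysis
IMMUNE_CELL_TYPES = ("T_cell", "CD8_T", "B_cell", "myeloid")

#: genes every spatial panel must declare
REQUIRED_SPATIAL_PANEL = (
    "B2M", "MITF", "TYR", "MLANA", "PMEL", "PDCD1", "LAG3", "TIGIT", "HAVCR2",
)

CHECKPOINT_GENES = ("PDCD1", "LAG3", "TIGIT", "HAVCR2")
MELANIN_GENES = ("MITF", "TYR", "MLANA", "PMEL")


def _check_unique_nonempty(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if not isinstance(i, str) or not i.strip():
            raise FormatError(f"empty or non-string {what} identifier: {i!r}")
        if i in seen:
            raise FormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table.

    ``scale='raw'`` holds FPKM-like non-negative abundances; ``scale='log2'``
    holds log2(x + pseudocount) values.
    """

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise FormatError(f"unknown scale {self.scale!r}")
        _check_unique_nonempty(list(self.values.index.astype(str)), "gene")
        _check_unique_nonempty(list(self.values.columns.astype(str)), "sample")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise FormatError("expression values must be finite")
        if self.scale == "raw" and (arr < 0).any():
            raise FormatError("raw-scale expression values must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)].copy(), self.scale)


@dataclass
class SampleMetadata:
    """Per-sample clinical and experimental annotations."""

    sample_id: str
    patient_id: str
    tissue: str = "pdo"
    culture_type: str = "none"
    timepoint: str = "none"
    response: str = "unknown"
    survival_time: Optional[float] = None
    survival_event: Optional[int] = None

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise FormatError(f"unknown tissue {self.tissue!r}")
        if self.culture_type not in CULTURE_TYPES:
            raise FormatError(f"unknown culture_type {self.culture_type!r}")
        if self.timepoint not in TIMEPOINTS:
            raise FormatError(f"unknown timepoint {self.timepoint!r}")
        if self.response not in RESPONSES:
            raise FormatError(f"unknown response {self.response!r}")
        if (self.survival_time is None) != (self.survival_event is None):
            raise FormatError(
                f"sample {self.sample_id}: survival_time and survival_event "
                "must be present together"
            )
        if self.survival_time is not None:
            if self.survival_time < 0:
                raise FormatError(f"negative survival_time for {self.sample_id}")
            if self.survival_event not in (0, 1):
                raise FormatError(f"survival_event must be 0/1 for {self.sample_id}")


def validate_metadata(records: Sequence[SampleMetadata]) -> None:
    _check_unique_nonempty([r.sample_id for r in records], "sample")


def metadata_to_frame(records: Sequence[SampleMetadata]) -> pd.DataFrame:
    """Flatten metadata records into a DataFrame indexed by sample_id."""
    validate_metadata(records)
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    return df.set_index("sample_id", drop=False)


@dataclass
class GeneSet:
    name: str
    genes: list[str] = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        # empty gene lists are permitted in memory (e.g. a selection step that
        # keeps nothing); the GMT reader rejects empty sets at the IO boundary
        if not self.name:
            raise FormatError("gene set needs a non-empty name")
        _check_unique_nonempty(self.genes, f"gene (set {self.name})")


@dataclass
class CloneTable:
    """Per-sample TCR clonotype counts (VDJtools-like long format)."""

    records: pd.DataFrame  # columns: sample, clonotype, count

    def __post_init__(self) -> None:
        required = {"sample", "clonotype", "count"}
        missing = required - set(self.records.columns)
        if missing:
            raise FormatError(f"clone table missing columns: {sorted(missing)}")
        counts = self.records["count"]
        if len(self.records) == 0:
            raise FormatError("clone table is empty")
        if not np.issubdtype(counts.to_numpy().dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise FormatError("clone counts must be integers")
            self.records = self.records.assign(count=counts.astype(int))
        if (self.records["count"] < 1).any():
            bad = self.records.loc[self.records["count"] < 1].iloc[0]
            raise FormatError(
                f"clone count must be >= 1 (sample {bad['sample']}, "
                f"clonotype {bad['clonotype']})"
            )
        dup = self.records.duplicated(subset=["sample", "clonotype"])
        if dup.any():
            bad = self.records.loc[dup].iloc[0]
            raise FormatError(
                f"duplicate (sample, clonotype) pair: ({bad['sample']}, {bad['clonotype']})"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.records["sample"]))


@dataclass
class SpatialCellTable:
    """Positioned cells with per-gene counts for a declared panel.

    ``cells`` has columns cell_id, x, y, cell_type, optionally sample_id,
    plus one non-negative count column per panel gene.
    """

    cells: pd.DataFrame
    panel: tuple[str, ...] = REQUIRED_SPATIAL_PANEL

    def __post_init__(self) -> None:
        base = {"cell_id", "x", "y", "cell_type"}
        missing = base - set(self.cells.columns)
        if missing:
            raise FormatError(f"spatial table missing columns: {sorted(missing)}")
        missing_panel = [g for g in REQUIRED_SPATIAL_PANEL if g not in self.panel]
        if missing_panel:
            raise FormatError(f"panel must include {missing_panel}")
        missing_cols = [g for g in self.panel if g not in self.cells.columns]
        if missing_cols:
            raise FormatError(f"spatial table missing panel gene columns: {missing_cols}")
        _check_unique_nonempty(list(self.cells["cell_id"].astype(str)), "cell")
        xy = self.cells[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            raise FormatError("cell coordinates must be finite")
        for g in self.panel:
            col = self.cells[g].to_numpy()
            if not np.issubdtype(col.dtype, np.number) or (col < 0).any():
                raise FormatError(f"panel counts for {g} must be non-negative numbers")
        bad_types = set(self.cells["cell_type"]) - set(CELL_TYPES)
        if bad_types:
            raise FormatError(f"unknown cell types: {sorted(bad_types)}")
        if "sample_id" not in self.cells.columns:
            self.cells = self.cells.assign(sample_id="sample1")

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.cells["sample_id"]))


@dataclass
class GenePositionTable:
    """1-based inclusive genomic coordinates per gene (GFF convention)."""

    positions: pd.DataFrame  # columns: gene_id, chromosome, start, end

    def __post_init__(self) -> None:
        required = {"gene_id", "chromosome", "start", "end"}
        missing = required - set(self.positions.columns)
        if missing:
            raise FormatError(f"position table missing columns: {sorted(missing)}")
        _check_unique_nonempty(list(self.positions["gene_id"].astype(str)), "gene")
        start = self.positions["start"].to_numpy()
        end = self.positions["end"].to_numpy()
        if (start < 1).any():
            raise FormatError("gene start coordinates must be >= 1 (1-based)")
        if (end < start).any():
            bad = self.positions.loc[end < start].iloc[0]
            raise FormatError(f"gene {bad['gene_id']}: end < start")

    def ordered(self) -> pd.DataFrame:
        """Positions sorted by chromosome (natural order) then start."""

        def chrom_key(c: str) -> tuple[int, str]:
            c = str(c).removeprefix("chr")
            return (0, f"{int(c):09d}") if c.isdigit() else (1, c)

        df = self.positions.copy()
        df["_key"] = [chrom_key(c) for c in df["chromosome"]]
        df = df.sort_values(["_key", "start"], kind="stable").drop(columns="_key")
        return df.reset_index(drop=True)
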