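"""Spatial tumor/immune classification rules and checkpoint scoring.

Implements the rules used on the in-situ single-cell panel: a tumor cell is
"MHC-I high" when its log-transformed B2M expression reaches a threshold
(log2(count+1) >= 3 by default), "melanin low" when all four melanocytic
markers (MITF, TYR, MLANA, PMEL) are exactly zero; CD8 T cells receive a
composite checkpoint score over PDCD1, LAG3, TIGIT and HAVCR2; and tumor
MHC-I class is related to the distance to the nearest immune cell.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .errors import DomainError
from .types import (
    CHECKPOINT_GENES,
    IMMUNE_CELL_TYPES,
    MELANIN_GENES,
    SpatialCellTable,
)

logger = logging.getLogger(__name__)


def combine_tables(tables: Sequence[SpatialCellTable]) -> SpatialCellTable:
    """Concatenate spatial tables (e.g. two profiled lesions) into one."""
    return SpatialCellTable(pd.concat([t.cells for t in tables], ignore_index=True))


def classify_mhc1(
    table: SpatialCellTable,
    threshold: float = 3.0,
    log_base: float = 2.0,
) -> pd.Series:
    """Per-tumor-cell MHC-I class: 'high' iff log(B2M count + 1) >= threshold.

    The boundary is inclusive; with the defaults a B2M count of 7 gives
    log2(8) = 3 and is classified high. Only melanoma-labeled cells are
    classified.
    """
    tumor = table.cells.loc[table.cells["cell_type"] == "melanoma"]
    if len(tumor) == 0:
        logger.warning("no melanoma cells to classify")
        return pd.Series(dtype=object, name="mhc1_class")
    logged = np.log(tumor["B2M"].to_numpy(dtype=float) + 1.0) / np.log(log_base)
    cls = np.where(logged >= threshold, "high", "low")
    return pd.Series(cls, index=tumor["cell_id"].to_numpy(), name="mhc1_class")


def classify_melanin(table: SpatialCellTable) -> pd.Series:
    """Per-tumor-cell melanin class: 'low' iff MITF, TYR, MLANA and PMEL are
    all exactly zero; any expression of any marker makes the cell 'high'."""
    tumor = table.cells.loc[table.cells["cell_type"] == "melanoma"]
    if len(tumor) == 0:
        logger.warning("no melanoma cells to classify")
        return pd.Series(dtype=object, name="melanin_class")
    all_zero = (tumor[list(MELANIN_GENES)].to_numpy(dtype=float) == 0).all(axis=1)
    cls = np.where(all_zero, "low", "high")
    return pd.Series(cls, index=tumor["cell_id"].to_numpy(), name="melanin_class")


@dataclass
class CheckpointResult:
    per_cell: pd.DataFrame        # cell_id, sample_id, score
    sample_means: pd.Series
    statistic: Optional[float]    # two-sample Mann-Whitney U (when 2 samples)
    p_value: Optional[float]


def checkpoint_score(
    table: SpatialCellTable,
    cell_types: Sequence[str] = ("CD8_T",),
) -> CheckpointResult:
    """Composite checkpoint-molecule score per target cell.

    Score = mean of log2(count + 1) over PDCD1, LAG3, TIGIT and HAVCR2.
    When exactly two samples carry target cells, their score distributions
    are compared with a two-sided Mann-Whitney U test.
    """
    target = table.cells.loc[table.cells["cell_type"].isin(cell_types)]
    if len(target) == 0:
        raise DomainError(f"no cells of type {list(cell_types)} in table")
    logged = np.log2(target[list(CHECKPOINT_GENES)].to_numpy(dtype=float) + 1.0)
    per_cell = pd.DataFrame({
        "cell_id": target["cell_id"].to_numpy(),
        "sample_id": target["sample_id"].to_numpy(),
        "score": logged.mean(axis=1),
    })
    empty = set(table.sample_ids) - set(per_cell["sample_id"])
    if empty:
        logger.warning("samples without target cells excluded: %s", sorted(empty))
    sample_means = per_cell.groupby("sample_id")["score"].mean()
    statistic = p_value = None
    samples = list(sample_means.index)
    if len(samples) == 2:
        a = per_cell.loc[per_cell["sample_id"] == samples[0], "score"]
        b = per_cell.loc[per_cell["sample_id"] == samples[1], "score"]
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        statistic, p_value = float(res.statistic), float(res.pvalue)
    return CheckpointResult(per_cell=per_cell, sample_means=sample_means,
                            statistic=statistic, p_value=p_value)


def nearest_immune_distance(
    table: SpatialCellTable,
    immune_types: Sequence[str] = IMMUNE_CELL_TYPES,
) -> pd.Series:
    """Euclidean distance from each tumor cell to its nearest immune cell."""
    immune = table.cells.loc[table.cells["cell_type"].isin(immune_types)]
    if len(immune) == 0:
        raise DomainError("no immune cells in table")
    tumor = table.cells.loc[table.cells["cell_type"] == "melanoma"]
    tree = cKDTree(immune[["x", "y"]].to_numpy(dtype=float))
    d, _ = tree.query(tumor[["x", "y"]].to_numpy(dtype=float))
    return pd.Series(d, index=tumor["cell_id"].to_numpy(), name="immune_distance")


@dataclass
class ProximityResult:
    per_cell: pd.DataFrame        # cell_id, mhc1_class, immune_distance, b2m_log
    rank_statistic: float         # MHC-I high vs low distance rank-sum
    rank_p: float
    spearman_rho: float           # log2(B2M+1) vs immune distance
    spearman_p: float


def proximity_association(
    table: SpatialCellTable,
    threshold: float = 3.0,
    immune_types: Sequence[str] = IMMUNE_CELL_TYPES,
) -> ProximityResult:
    """Is antigen presentation on tumor cells spatially coupled to immune
    infiltration? Compares the immune distance of MHC-I-high vs -low tumor
    cells (two-sided rank-sum) and reports the Spearman correlation of
    log2(B2M + 1) with immune distance."""
    mhc1 = classify_mhc1(table, threshold=threshold)
    dist = nearest_immune_distance(table, immune_types=immune_types)
    tumor = table.cells.loc[table.cells["cell_type"] == "melanoma"]
    per_cell = pd.DataFrame({
        "cell_id": tumor["cell_id"].to_numpy(),
        "mhc1_class": mhc1.to_numpy(),
        "immune_distance": dist.to_numpy(),
        "b2m_log": np.log2(tumor["B2M"].to_numpy(dtype=float) + 1.0),
    })
    hi = per_cell.loc[per_cell["mhc1_class"] == "high", "immune_distance"]
    lo = per_cell.loc[per_cell["mhc1_class"] == "low", "immune_distance"]
    if len(hi) < 2 or len(lo) < 2:
        raise DomainError("need >= 2 tumor cells in each MHC-I class")
    rank = stats.ranksums(hi, lo)
    rho = stats.spearmanr(per_cell["b2m_log"], per_cell["immune_distance"])
    return ProximityResult(
        per_cell=per_cell,
        rank_statistic=float(rank.statistic),
        rank_p=float(rank.pvalue),
        spearman_rho=float(rho.statistic),
        spearman_p=float(rho.pvalue),
    )
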