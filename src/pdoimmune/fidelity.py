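"""Organoid-tumor fidelity analyses.

Do organotypic cultures preserve the transcriptome, immune composition and
copy-number landscape of the metastasis they were derived from? This module
answers with four instruments: top-variable-gene PCA, composite gene-set /
microenvironment-population scores, a matched-vs-unmatched correlation test,
and a windowed expression-derived copy-number profiler against a panel of
reference samples.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import DomainError, StateError
from .types import ExpressionMatrix, GenePositionTable, GeneSet, SampleMetadata, metadata_to_frame

logger = logging.getLogger(__name__)


def log_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) on a raw-scale matrix."""
    if matrix.scale != "raw":
        raise StateError("matrix is already on log2 scale")
    return ExpressionMatrix(np.log2(matrix.values + pseudocount), scale="log2")


def ensure_log(matrix: ExpressionMatrix) -> ExpressionMatrix:
    return matrix if matrix.scale == "log2" else log_transform(matrix)


def geneset_score(matrix: ExpressionMatrix, gene_set: GeneSet) -> pd.Series:
    """Composite score: mean per-gene z-score of log2 expression across samples.

    Zero-variance genes contribute 0 so that score dimensionality is stable;
    genes absent from the matrix are dropped with a warning.
    """
    if matrix.scale != "log2":
        raise StateError("geneset_score expects a log2-scale matrix")
    if matrix.values.shape[1] < 2:
        raise DomainError("geneset_score needs >= 2 samples")
    present = [g for g in gene_set.genes if g in matrix.values.index]
    absent = [g for g in gene_set.genes if g not in matrix.values.index]
    if not present:
        raise DomainError(
            f"no overlap between gene set {gene_set.name!r} and matrix "
            f"(looked for {gene_set.genes})"
        )
    if absent:
        logger.warning("gene set %s: dropping %d absent genes: %s",
                       gene_set.name, len(absent), absent)
    sub = matrix.values.loc[present]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=0)
    z = sub.sub(mu, axis=0).div(sd.where(sd > 0, np.inf), axis=0)
    score = z.mean(axis=0)
    score.name = gene_set.name
    return score


def mcp_scores(matrix: ExpressionMatrix, population_sets: Sequence[GeneSet]) -> pd.DataFrame:
    """Samples x populations table of composite scores (MCP-counter style)."""
    matrix = ensure_log(matrix)
    cols = {}
    for s in population_sets:
        cols[s.name] = geneset_score(matrix, s)
    return pd.DataFrame(cols, index=matrix.values.columns)


@dataclass
class PcaResult:
    coordinates: pd.DataFrame          # samples x components
    variance_fractions: np.ndarray     # per retained component
    genes_used: list[str]


def top_variable_genes(matrix: ExpressionMatrix, n_genes: int) -> list[str]:
    variances = matrix.values.var(axis=1, ddof=0)
    n = min(n_genes, len(variances))
    return list(variances.sort_values(ascending=False, kind="stable").index[:n])


def top_variable_pca(matrix: ExpressionMatrix, n_genes: int = 5000,
                     n_components: int = 2) -> PcaResult:
    """PCA of the most variable genes, the standard first look at whether
    organoids and their source tumors co-locate in transcriptional space."""
    matrix = ensure_log(matrix)
    n_samples = matrix.values.shape[1]
    if n_samples < 3:
        raise DomainError("top_variable_pca needs >= 3 samples")
    genes = top_variable_genes(matrix, n_genes)
    sub = matrix.values.loc[genes].T  # samples x genes
    n_components = min(n_components, n_samples - 1, len(genes))
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(sub.to_numpy() - sub.to_numpy().mean(axis=0))
    coordinates = pd.DataFrame(
        coords, index=sub.index, columns=[f"PC{i + 1}" for i in range(n_components)]
    )
    return PcaResult(coordinates=coordinates,
                     variance_fractions=pca.explained_variance_ratio_,
                     genes_used=genes)


@dataclass
class CorrelationReport:
    pairs: pd.DataFrame       # columns: pdo_sample, met_sample, correlation, matched
    statistic: float
    p_value: float
    method: str
    n_top_genes: int

    @property
    def matched(self) -> pd.Series:
        return self.pairs.loc[self.pairs["matched"], "correlation"]

    @property
    def unmatched(self) -> pd.Series:
        return self.pairs.loc[~self.pairs["matched"], "correlation"]


def matched_correlation_test(
    matrix: ExpressionMatrix,
    metadata: Sequence[SampleMetadata],
    n_top_genes: int = 5000,
    method: str = "pearson",
) -> CorrelationReport:
    """Are organoids transcriptionally closer to their own metastasis than to
    unrelated ones?

    Computes the correlation between every (PDO, metastasis) pair on the
    log2 values of the top-variable genes and compares matched vs unmatched
    correlations with a two-sided Mann-Whitney U test.
    """
    if method not in ("pearson", "spearman"):
        raise DomainError(f"unknown correlation method {method!r}")
    meta = metadata_to_frame(metadata)
    meta = meta.loc[meta["sample_id"].isin(matrix.sample_ids)]
    pdos = meta.loc[(meta["tissue"] == "pdo") & (meta["timepoint"] != "stimulated")]
    mets = meta.loc[meta["tissue"] == "metastasis"]
    dup = pdos.groupby(["patient_id", "timepoint"]).size()
    if (dup > 1).any():
        patient = dup[dup > 1].index[0]
        raise DomainError(
            f"patient {patient[0]} has multiple PDO samples at timepoint "
            f"{patient[1]}; disambiguate before the matched-correlation test"
        )
    matched_patients = set(pdos["patient_id"]) & set(mets["patient_id"])
    if len(matched_patients) < 2:
        raise DomainError("need >= 2 patients with both a PDO and a metastasis")
    logm = ensure_log(matrix)
    genes = top_variable_genes(logm, n_top_genes)
    sub = logm.values.loc[genes]
    rows = []
    for (_, p), (_, m) in itertools.product(pdos.iterrows(), mets.iterrows()):
        x = sub[p["sample_id"]].to_numpy()
        y = sub[m["sample_id"]].to_numpy()
        if method == "pearson":
            r = stats.pearsonr(x, y).statistic
        else:
            r = stats.spearmanr(x, y).statistic
        rows.append({
            "pdo_sample": p["sample_id"],
            "met_sample": m["sample_id"],
            "correlation": float(r),
            "matched": p["patient_id"] == m["patient_id"],
        })
    pairs = pd.DataFrame(rows)
    res = stats.mannwhitneyu(
        pairs.loc[pairs["matched"], "correlation"],
        pairs.loc[~pairs["matched"], "correlation"],
        alternative="two-sided",
    )
    return CorrelationReport(pairs=pairs, statistic=float(res.statistic),
                             p_value=float(res.pvalue), method=method,
                             n_top_genes=len(genes))


@dataclass
class CnvProfile:
    sample_id: str
    bins: pd.DataFrame          # gene_id, chromosome, start, log2_ratio, smoothed
    chromosome_means: pd.Series
    calls: pd.Series            # per chromosome: loss / neutral / gain


def cnv_profile(
    matrix: ExpressionMatrix,
    positions: GenePositionTable,
    reference_samples: Sequence[str],
    window: int = 101,
    call_threshold: float = 0.15,
    winsor: float = 3.0,
) -> dict[str, CnvProfile]:
    """Expression-derived copy-number profiles against reference samples.

    A deliberate simplification of HMM-based inference: per gene, the log2
    value minus the reference mean, winsorized to +-``winsor``; per
    chromosome, a centered moving average (edge windows truncated); a
    chromosome is called loss/gain when its mean ratio crosses
    -+``call_threshold``.
    """
    if len(reference_samples) < 3:
        raise DomainError("cnv_profile needs >= 3 reference samples")
    missing = [s for s in reference_samples if s not in matrix.sample_ids]
    if missing:
        raise DomainError(f"reference samples not in matrix: {missing}")
    logm = ensure_log(matrix)
    pos = positions.ordered()
    pos = pos.loc[pos["gene_id"].isin(logm.values.index)]
    if len(pos) == 0:
        raise DomainError("no positioned genes overlap the matrix")
    ordered_genes = list(pos["gene_id"])
    sub = logm.values.loc[ordered_genes]
    ref_mean = sub[list(reference_samples)].mean(axis=1)
    profiles: dict[str, CnvProfile] = {}
    query_samples = [s for s in logm.sample_ids if s not in set(reference_samples)]
    for sample in query_samples:
        ratio = (sub[sample] - ref_mean).clip(-winsor, winsor)
        bins = pos[["gene_id", "chromosome", "start"]].copy()
        bins["log2_ratio"] = ratio.to_numpy()
        smoothed = (
            bins.groupby("chromosome", sort=False)["log2_ratio"]
            .transform(lambda s: s.rolling(window, center=True, min_periods=1).mean())
        )
        bins["smoothed"] = smoothed
        chrom_means = bins.groupby("chromosome", sort=False)["log2_ratio"].mean()
        calls = pd.Series(
            np.select(
                [chrom_means <= -call_threshold, chrom_means >= call_threshold],
                ["loss", "gain"],
                default="neutral",
            ),
            index=chrom_means.index,
        )
        profiles[sample] = CnvProfile(sample_id=sample, bins=bins,
                                      chromosome_means=chrom_means, calls=calls)
    return profiles
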