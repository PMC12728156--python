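"""TCR repertoire summaries: clone counting, expansion, diversity, and the
clonality-expression correlation.

"Specific clones" are clonotypes seen at least ``min_count`` times
(default 2), separating recurrent clones from singletons. Diversity is
reported as Shannon entropy (nats), normalized Shannon (entropy / ln
richness), and inverse Simpson — the usual repertoire statistics.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .types import CloneTable, SampleMetadata, metadata_to_frame

logger = logging.getLogger(__name__)


def repertoire_summary(clones: CloneTable, min_count: int = 2) -> pd.DataFrame:
    """Per-sample repertoire statistics.

    Columns: total_reads, distinct_clonotypes, specific_clones (count >=
    min_count), shannon (nats), normalized_shannon (0 for a single-clone
    repertoire), inverse_simpson.
    """
    if min_count < 1:
        raise DomainError("min_count must be >= 1")
    rows = []
    for sample, grp in clones.records.groupby("sample", sort=True):
        # sort descending so summaries are exactly permutation-invariant
        counts = np.sort(grp["count"].to_numpy(dtype=float))[::-1]
        total = counts.sum()
        p = counts / total
        shannon = float(-(p * np.log(p)).sum())
        richness = len(counts)
        normalized = shannon / np.log(richness) if richness > 1 else 0.0
        inv_simpson = float(1.0 / (p ** 2).sum())
        rows.append({
            "sample": sample,
            "total_reads": int(total),
            "distinct_clonotypes": richness,
            "specific_clones": int((counts >= min_count).sum()),
            "shannon": shannon,
            "normalized_shannon": float(normalized),
            "inverse_simpson": inv_simpson,
        })
    return pd.DataFrame(rows).set_index("sample")


@dataclass
class ExpansionResult:
    per_patient: pd.DataFrame   # patient, response, baseline, stimulated, delta
    group_means: pd.Series      # response -> mean delta


def expansion_delta(
    summaries: pd.DataFrame,
    metadata: Sequence[SampleMetadata],
    column: str = "specific_clones",
) -> ExpansionResult:
    """Per-patient change in specific-clone count from baseline to
    stimulated culture, grouped by ICB response."""
    meta = metadata_to_frame(metadata)
    meta = meta.loc[meta["sample_id"].isin(summaries.index)]
    rows = []
    for patient, grp in meta.groupby("patient_id"):
        base = grp.loc[grp["timepoint"] == "baseline", "sample_id"]
        stim = grp.loc[grp["timepoint"] == "stimulated", "sample_id"]
        if len(base) != 1 or len(stim) != 1:
            continue
        b = float(summaries.loc[base.iloc[0], column])
        s = float(summaries.loc[stim.iloc[0], column])
        rows.append({"patient_id": patient, "response": grp["response"].iloc[0],
                     "baseline": b, "stimulated": s, "delta": s - b})
    if not rows:
        raise DomainError("no patient has clone summaries at both timepoints")
    df = pd.DataFrame(rows)
    return ExpansionResult(per_patient=df,
                           group_means=df.groupby("response")["delta"].mean())


def clonality_expression_correlation(
    summaries: pd.DataFrame,
    tcell_scores: pd.Series,
    column: str = "specific_clones",
) -> tuple[float, float]:
    """Spearman correlation between per-sample specific-clone counts and the
    T-cell expression score, across samples present in both inputs."""
    common = [s for s in summaries.index if s in tcell_scores.index]
    if len(common) < 4:
        raise DomainError("need >= 4 samples present in both inputs")
    res = stats.spearmanr(summaries.loc[common, column].to_numpy(dtype=float),
                          tcell_scores.loc[common].to_numpy(dtype=float))
    return float(res.statistic), float(res.pvalue)
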