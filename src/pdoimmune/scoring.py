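"""Signature scoring, response-group deltas, and survival stratification.

The composite score of a gene signature is the mean of per-gene z-scores of
log2 expression across the cohort (see :func:`pdoimmune.fidelity.geneset_score`),
which makes scores comparable across cohorts with different depth
conventions. Scored cohorts are compared by paired pre/on-treatment deltas
across ICB response groups and stratified into score tertiles for
Kaplan-Meier / log-rank survival analysis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats

from .errors import DomainError
from .fidelity import ensure_log, geneset_score
from .types import ExpressionMatrix, GeneSet, SampleMetadata, metadata_to_frame

logger = logging.getLogger(__name__)


def score_cohort(matrix: ExpressionMatrix, signature: GeneSet) -> pd.Series:
    """Per-sample composite signature score (mean per-gene z-score of log2
    expression). Missing signature genes are logged and dropped."""
    if not signature.genes:
        raise DomainError("cannot score with an empty signature")
    return geneset_score(ensure_log(matrix), signature)


@dataclass
class DeltaResult:
    per_patient: pd.DataFrame     # patient, response, pre, on, delta
    group_means: pd.Series        # response -> mean delta
    statistic: Optional[float]
    p_value: Optional[float]


def pre_on_delta(
    scores: pd.Series,
    metadata: Sequence[SampleMetadata],
) -> DeltaResult:
    """Per-patient on-minus-pre score deltas, compared across response groups.

    Benefit (stable disease / partial response / complete response, mapped
    to ``responder``) vs no benefit (progressive disease, mapped to
    ``non_responder``), two-sided rank-sum on the deltas. With a single
    group present the summary is still produced and the test skipped.
    """
    meta = metadata_to_frame(metadata)
    meta = meta.loc[meta["sample_id"].isin(scores.index)]
    rows = []
    for patient, grp in meta.groupby("patient_id"):
        pre = grp.loc[grp["timepoint"].isin(("pre_treatment", "baseline")), "sample_id"]
        on = grp.loc[grp["timepoint"].isin(("on_treatment", "stimulated")), "sample_id"]
        if len(pre) > 1 or len(on) > 1:
            raise DomainError(
                f"patient {patient} has duplicate timepoint samples; disambiguate"
            )
        if len(pre) != 1 or len(on) != 1:
            continue
        rows.append({
            "patient_id": patient,
            "response": grp["response"].iloc[0],
            "pre": float(scores[pre.iloc[0]]),
            "on": float(scores[on.iloc[0]]),
        })
    if len(rows) < 2:
        raise DomainError("need >= 2 patients with both pre and on samples")
    df = pd.DataFrame(rows)
    df["delta"] = df["on"] - df["pre"]
    group_means = df.groupby("response")["delta"].mean()
    benefit = df.loc[df["response"] == "responder", "delta"]
    no_benefit = df.loc[df["response"] == "non_responder", "delta"]
    if len(benefit) >= 2 and len(no_benefit) >= 2:
        res = stats.mannwhitneyu(benefit, no_benefit, alternative="two-sided")
        statistic, p_value = float(res.statistic), float(res.pvalue)
    else:
        logger.warning("only one response group with pre/on pairs; rank-sum test skipped")
        statistic = p_value = None
    return DeltaResult(per_patient=df, group_means=group_means,
                       statistic=statistic, p_value=p_value)


def tertile_stratify(scores: pd.Series) -> pd.Series:
    """Rank-based tertile labels (low/mid/high), sizes differing by <= 1.

    Remainders go to the low tertile first; ties are broken by stable
    patient-id order, so the split is deterministic.
    """
    if len(scores) < 3:
        raise DomainError("tertile stratification needs >= 3 patients")
    order = sorted(scores.index, key=lambda pid: (scores[pid], str(pid)))
    n = len(order)
    base, rem = divmod(n, 3)
    n_low = base + (1 if rem >= 1 else 0)
    n_mid = base + (1 if rem >= 2 else 0)
    labels = {}
    for i, pid in enumerate(order):
        labels[pid] = "low" if i < n_low else ("mid" if i < n_low + n_mid else "high")
    return pd.Series(labels, name="tertile").loc[scores.index]


@dataclass
class SurvivalStratification:
    table: pd.DataFrame                 # patient, score-group, time, event
    statistic: float                    # k-group log-rank
    p_value: float
    degrees_of_freedom: int
    high_vs_low_statistic: Optional[float]
    high_vs_low_p: Optional[float]
    curves: dict                        # group -> DataFrame(time, at_risk, survival)


def km_logrank(
    time: Sequence[float],
    event: Sequence[int],
    group: Sequence[str],
) -> SurvivalStratification:
    """Kaplan-Meier curves per group plus the k-group log-rank test.

    Also reports the pairwise high-vs-low log-rank when groups named
    'high' and 'low' are present.
    """
    df = pd.DataFrame({"time": np.asarray(time, dtype=float),
                       "event": np.asarray(event, dtype=int),
                       "group": list(group)})
    if df["time"].lt(0).any():
        raise DomainError("negative survival times")
    groups = [g for g in pd.unique(df["group"])]
    if len(groups) < 2:
        raise DomainError("log-rank needs >= 2 groups")
    events_per_group = df.groupby("group")["event"].sum()
    if (events_per_group < 1).any():
        lacking = list(events_per_group.index[events_per_group < 1])
        raise DomainError(f"groups without any event: {lacking}")
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    curves = {}
    for g, sub in df.groupby("group"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(g))
        ev = kmf.event_table
        curves[g] = pd.DataFrame({
            "time": ev.index.to_numpy(dtype=float),
            "at_risk": ev["at_risk"].to_numpy(dtype=int),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
        })
    hvl_stat = hvl_p = None
    if "high" in groups and "low" in groups:
        hi = df.loc[df["group"] == "high"]
        lo = df.loc[df["group"] == "low"]
        pair = logrank_test(hi["time"], lo["time"], hi["event"], lo["event"])
        hvl_stat, hvl_p = float(pair.test_statistic), float(pair.p_value)
    return SurvivalStratification(
        table=df,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        degrees_of_freedom=len(groups) - 1,
        high_vs_low_statistic=hvl_stat,
        high_vs_low_p=hvl_p,
        curves=curves,
    )


def survival_by_score_tertile(
    matrix: ExpressionMatrix,
    metadata: Sequence[SampleMetadata],
    signature: GeneSet,
    timepoint: str = "pre_treatment",
) -> tuple[pd.Series, SurvivalStratification]:
    """Score the cohort, stratify patients into score tertiles, and run the
    Kaplan-Meier / log-rank analysis on the samples carrying survival data."""
    meta = metadata_to_frame(metadata)
    surv = meta.loc[meta["survival_time"].notna() & (meta["timepoint"] == timepoint)]
    if len(surv) < 3:
        raise DomainError("need >= 3 patients with survival annotations")
    scores = score_cohort(matrix.subset_samples(surv["sample_id"]), signature)
    per_patient = pd.Series(scores.to_numpy(), index=surv["patient_id"].to_numpy())
    tertiles = tertile_stratify(per_patient)
    strat = km_logrank(surv["survival_time"].to_numpy(),
                       surv["survival_event"].to_numpy(dtype=int),
                       tertiles.to_numpy())
    return tertiles, strat
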