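import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pdoimmune import scoring, simulate as sim
from pdoimmune.errors import DomainError
from pdoimmune.types import ExpressionMatrix, GeneSet, SampleMetadata


def brute_force_logrank(time, event, group):
    """Independent risk-set computation of the 2-group log-rank statistic.

    At each distinct event time, observed-vs-expected events in group A
    under the hypergeometric risk-set model; chi-square with 1 df.
    """
    df = pd.DataFrame({"t": time, "e": event, "g": group})
    groups = sorted(set(group))
    a = groups[0]
    O = E = V = 0.0
    for t in sorted(df.loc[df["e"] == 1, "t"].unique()):
        at_risk = df.loc[df["t"] >= t]
        n = len(at_risk)
        n_a = (at_risk["g"] == a).sum()
        d = ((df["t"] == t) & (df["e"] == 1)).sum()
        d_a = ((df["t"] == t) & (df["e"] == 1) & (df["g"] == a)).sum()
        O += d_a
        E += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V if V > 0 else 0.0
    return chi2, 1 - sps.chi2.cdf(chi2, 1)


class TestScoreCohort:
    def test_single_gene_reduction(self, toy_matrix):
        score = scoring.score_cohort(
            ExpressionMatrix(2 ** toy_matrix.values - 1, "raw"),
            GeneSet("one", ["gA"]))
        log = toy_matrix.values.loc["gA"]
        expected = (log - log.mean()) / log.std(ddof=0)
        assert np.allclose(score, expected)

    def test_cohort_mean_zero(self, default_bulk):
        matrix, _, truth = default_bulk
        score = scoring.score_cohort(matrix, GeneSet("sig", truth.signature_genes))
        assert abs(score.mean()) < 1e-9

    def test_invariance_to_gene_order_and_absent_genes(self, default_bulk):
        matrix, _, truth = default_bulk
        genes = truth.signature_genes
        a = scoring.score_cohort(matrix, GeneSet("s", genes))
        b = scoring.score_cohort(matrix, GeneSet("s", genes[::-1] + ["NOT_A_GENE"]))
        assert np.allclose(a, b)

    def test_planted_high_scores_reach_top_tertile(self):
        """Patients planted in the top score tertile are recovered there from
        the measured composite score in >= 90% of cases."""
        rates = []
        for seed in range(5):
            cfg = sim.SimulationConfig(seed=seed, n_validation_patients=90)
            matrix, metadata, truth = sim.simulate_validation(cfg)
            pre = [m for m in metadata if m.timepoint == "pre_treatment"]
            scores = scoring.score_cohort(
                matrix.subset_samples([m.sample_id for m in pre]),
                GeneSet("sig", truth.signature_genes))
            per_patient = pd.Series(scores.to_numpy(),
                                    index=[m.patient_id for m in pre])
            measured = scoring.tertile_stratify(per_patient)
            planted_high = [p for p, t in truth.planted_tertiles.items() if t == "high"]
            rates.append((measured.loc[planted_high] == "high").mean())
        assert np.mean(rates) >= 0.90


class TestPreOnDelta:
    def test_identical_matrices_null(self):
        rng = np.random.default_rng(8)
        meta, cols = [], {}
        for i in range(6):
            resp = "responder" if i < 3 else "non_responder"
            profile = rng.uniform(0, 50, 30)
            for tp, tag in (("pre_treatment", "PRE"), ("on_treatment", "ON")):
                sid = f"V{i}_{tag}"
                cols[sid] = profile  # on == pre exactly
                meta.append(SampleMetadata(sample_id=sid, patient_id=f"V{i}",
                                           tissue="metastasis", timepoint=tp,
                                           response=resp))
        m = ExpressionMatrix(pd.DataFrame(cols, index=[f"g{i}" for i in range(30)]))
        scores = scoring.score_cohort(m, GeneSet("s", ["g0", "g1", "g2"]))
        res = scoring.pre_on_delta(scores, meta)
        assert np.allclose(res.per_patient["delta"], 0.0)
        assert res.p_value == 1.0

    def test_single_group_skips_test(self):
        rng = np.random.default_rng(9)
        meta, cols = [], {}
        for i in range(3):
            for tp, tag in (("pre_treatment", "PRE"), ("on_treatment", "ON")):
                sid = f"V{i}_{tag}"
                cols[sid] = rng.uniform(0, 9, 10)
                meta.append(SampleMetadata(sample_id=sid, patient_id=f"V{i}",
                                           tissue="metastasis", timepoint=tp,
                                           response="responder"))
        m = ExpressionMatrix(pd.DataFrame(cols, index=[f"g{i}" for i in range(10)]))
        scores = scoring.score_cohort(m, GeneSet("s", ["g0", "g1"]))
        res = scoring.pre_on_delta(scores, meta)
        assert res.p_value is None
        assert "responder" in res.group_means

    def test_duplicate_timepoint_rejected(self):
        meta = [
            SampleMetadata(sample_id="a", patient_id="V1", timepoint="pre_treatment"),
            SampleMetadata(sample_id="b", patient_id="V1", timepoint="pre_treatment"),
            SampleMetadata(sample_id="c", patient_id="V1", timepoint="on_treatment"),
        ]
        scores = pd.Series([0.0, 1.0, 2.0], index=["a", "b", "c"])
        with pytest.raises(DomainError, match="V1"):
            scoring.pre_on_delta(scores, meta)


class TestTertiles:
    def test_exact_thirds(self):
        s = pd.Series({i: float(i) for i in range(1, 10)})
        t = scoring.tertile_stratify(s)
        assert set(t[t == "low"].index) == {1, 2, 3}
        assert set(t[t == "mid"].index) == {4, 5, 6}
        assert set(t[t == "high"].index) == {7, 8, 9}

    def test_remainder_goes_low_first(self):
        s = pd.Series({f"p{i}": float(i) for i in range(10)})
        t = scoring.tertile_stratify(s)
        sizes = t.value_counts()
        assert sizes["low"] == 4 and sizes["mid"] == 3 and sizes["high"] == 3

    def test_all_tied_scores_balanced(self):
        s = pd.Series({f"p{i}": 1.0 for i in range(8)})
        t = scoring.tertile_stratify(s)
        assert t.value_counts().max() - t.value_counts().min() <= 1

    def test_deterministic_under_ties(self):
        s = pd.Series({f"p{i}": i % 2 * 1.0 for i in range(9)})
        assert scoring.tertile_stratify(s).equals(scoring.tertile_stratify(s))

    def test_too_few_rejected(self):
        with pytest.raises(DomainError):
            scoring.tertile_stratify(pd.Series({"a": 1.0, "b": 2.0}))


class TestKmLogrank:
    def test_identical_groups_null(self):
        res = scoring.km_logrank([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1],
                                 ["A", "A", "A", "B", "B", "B"])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_four_subjects(self):
        """O_A=2, E_A=1/2+1/3, V=1/4+2/9 -> chi2=(7/6)^2/(17/36)=2.88235."""
        res = scoring.km_logrank([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert res.statistic == pytest.approx(2.8823529411764706, rel=1e-9)
        assert res.p_value == pytest.approx(0.08955507441364241, rel=1e-6)

    def test_agrees_with_brute_force_on_small_instances(self):
        """Exhaustive oracle check on all two-group datasets of <= 8 subjects."""
        rng = np.random.default_rng(10)
        checked = 0
        for n in (4, 6, 8):
            for _ in range(40):
                time = rng.integers(1, 6, n).astype(float)
                event = rng.integers(0, 2, n)
                group = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
                if event[group == "A"].sum() < 1 or event[group == "B"].sum() < 1:
                    continue
                res = scoring.km_logrank(time, event, group)
                chi2, p = brute_force_logrank(time, event, group)
                assert res.statistic == pytest.approx(chi2, rel=1e-8)
                assert res.p_value == pytest.approx(p, rel=1e-6)
                checked += 1
        assert checked > 50

    def test_km_curves_monotone_from_one(self):
        rng = np.random.default_rng(11)
        res = scoring.km_logrank(rng.exponential(10, 40), rng.integers(0, 2, 40),
                                 ["A"] * 20 + ["B"] * 20)
        for curve in res.curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert (np.diff(s) <= 1e-12).all()

    def test_no_events_rejected(self):
        with pytest.raises(DomainError):
            scoring.km_logrank([1, 2, 3, 4], [0, 0, 0, 0], ["A", "A", "B", "B"])

    def test_planted_hazard_detected(self):
        cfg = sim.SimulationConfig(seed=14, n_genes=120, n_validation_patients=300)
        matrix, metadata, truth = sim.simulate_validation(cfg)
        _, strat = scoring.survival_by_score_tertile(
            matrix, metadata, GeneSet("sig", truth.signature_genes))
        assert strat.p_value < 0.05
        assert strat.degrees_of_freedom == 2
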