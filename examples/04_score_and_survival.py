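"""Validate a signature on an independent cohort: pre/on-treatment deltas
by response group, then tertile survival stratification.

The composite score is the mean per-gene z-score of log2 expression. In the
synthetic validation cohort, responders receive the activation program in
their on-treatment sample and survival hazard is tied to the planted score.
"""
from pdoimmune import GeneSet, SimulationConfig, pre_on_delta, score_cohort
from pdoimmune import simulate as sim
from pdoimmune.scoring import survival_by_score_tertile

config = SimulationConfig(seed=1, n_validation_patients=300)
matrix, metadata, truth = sim.simulate_validation(config)
signature = GeneSet("tcell_signature", truth.signature_genes)

scores = score_cohort(matrix, signature)
delta = pre_on_delta(scores, metadata)
print("mean on-minus-pre score delta by response group:")
for group, mean in delta.group_means.items():
    print(f"  {group:14s} {mean:+.3f}")
print(f"rank-sum p = {delta.p_value:.2e}")
# The score rises on treatment only in patients with clinical benefit.

tertiles, strat = survival_by_score_tertile(matrix, metadata, signature)
print(f"tertile sizes: {tertiles.value_counts().to_dict()}")
print(f"3-group log-rank: chi2 = {strat.statistic:.1f} "
      f"({strat.degrees_of_freedom} df), p = {strat.p_value:.2e}")
print(f"high-vs-low log-rank p = {strat.high_vs_low_p:.2e}")
# High-score tertiles live longer: the planted hazard ratio (0.4 high vs
# low) is recovered by stratifying on the measured score.
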