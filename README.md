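# pdoimmune

Immuno-transcriptomic analysis of patient-derived organotypic cultures
(PDOs) from metastatic melanoma. PDOs preserve tumor and immune cells from
fresh surgical tissue; stimulating their T cells ex vivo (CD3/CD28 agonism
plus PD1 blockade) and reading out the transcriptome makes the culture a
functional assay of a patient's capacity to mount an anti-tumor immune
response. This package implements that analysis as a reusable, tested
pipeline for translational immuno-oncology groups:

- **Fidelity** — does the organoid preserve its source metastasis?
  Top-variable-gene PCA, microenvironment population (MCP-style) scores,
  a matched-vs-unmatched correlation test, and expression-derived
  copy-number profiles against a reference panel.
- **Signature discovery** — per-patient log2 fold changes between baseline
  and stimulated cultures; genes induced in ICB responders but flat in
  non-responders; filtered to genes expressed exclusively in T cells in
  single-cell data.
- **Signature scoring & survival** — composite score = mean per-gene
  z-score of log2 expression, `s_j = (1/|G|) Σ_{g∈G} (x_gj − μ_g)/σ_g`;
  pre/on-treatment deltas by response group (rank-sum test) and score-
  tertile Kaplan–Meier / log-rank stratification.
- **Spatial rules** — tumor cells are "MHC-I high" iff log2(B2M + 1) ≥ 3,
  "melanin low" iff MITF, TYR, MLANA and PMEL are all zero; CD8 checkpoint
  score over PDCD1/LAG3/TIGIT/HAVCR2; MHC-I class vs distance to the
  nearest immune cell.
- **TCR clonality** — specific-clone counts (count ≥ 2), Shannon/inverse-
  Simpson diversity, responder-restricted expansion, and the Spearman
  coupling between clonality and T-cell expression score.
- **Synthetic cohorts** — a first-class generator that plants every one of
  these effects with known ground truth, so the whole pipeline is testable
  end-to-end without patient data (which cannot be publicly shared for
  studies of this kind).

## Worked example

Discover the planted T-cell activation signature from a synthetic
stimulation cohort (`examples/03_discover_signature.py`):

```python
from pdoimmune import SimulationConfig, discover_signature
from pdoimmune import simulate as sim

config = SimulationConfig(seed=1)
matrix, metadata, truth = sim.simulate_bulk(config)
cells = sim.simulate_cells(config)
result = discover_signature(matrix, metadata, cells)
```

prints

```
candidate genes after fold-change selection: 15
final T-cell-exclusive signature (13 genes): CCL1 CTLA4 CXCL13 ICOS TNFRSF4 ...
planted genes recovered: 13/14, false positives: 0
```

The generator induced a 14-gene program (CCL1, ICOS, CTLA4, CXCL13,
TNFRSF4/OX40 and nine generated names) only in stimulated responder
cultures; the discovery pipeline recovers 13 of them and admits no gene
expressed outside T cells. Validating that signature on an independent
synthetic cohort (`examples/04_score_and_survival.py`) yields a mean
on-minus-pre score delta of +0.83 in responders vs +0.003 in
non-responders (rank-sum p ≈ 1e-50 at n = 300) and a 3-group log-rank
χ² = 13.7 (p ≈ 1e-3) across score tertiles — high-score patients live
longer, as the planted hazard ratio of 0.4 dictates.

Each capability has a short narrative script under `examples/`; the
`pdoimmune` CLI (`simulate`, `fidelity`, `discover`, `score`, `survival`,
`spatial`, `tcr`, `run-all`) chains the same library functions over files
and writes a run manifest.

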