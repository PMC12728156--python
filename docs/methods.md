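# Methods

This note documents the models and procedures implemented in `pdoimmune`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic cohorts do and do not emulate.

## Composite gene-set scoring

All composite scores (microenvironment populations, antigen presentation,
melanocytic/dedifferentiated programs, and the discovered T-cell signature)
use the same statistic: on log2(x+1) expression, each gene is standardized
across the samples of the cohort (population SD; zero-variance genes
contribute 0 so score dimensionality is stable), and the score is the mean
z-score over the set's genes present in the matrix. Absent genes are
dropped with a warning. Z-scoring makes scores comparable across cohorts
with different depth conventions (FPKM vs counts-derived), which matters
when one signature is applied to several external cohorts; the price is
that scores are cohort-relative (mean 0 by construction) and should not be
compared as absolute values across cohorts.

The bundled `data/mcp_populations.gmt` is a compact curated marker file
(CD3D/CD3E/… for T cells, CD14/CD163/… for monocytes, COL1A1/… for
fibroblasts, etc.) in the spirit of marker-based microenvironment scoring.
It is deliberately small and editable; groups with their own marker panels
should supply their own GMT.

## Organoid–tumor fidelity

*Matched correlation.* For every (organoid, metastasis) pair the Pearson
correlation of log2 values over the 5,000 most variable genes is computed
(method and gene subset configurable; Spearman available). Matched pairs
(same patient) are compared with unmatched pairs by a two-sided
Mann–Whitney U test. The test is symmetric in patient labels, and under a
permuted-label null it rejects at its nominal rate (checked over 50 seeds
in the acceptance suite). Stimulated cultures are excluded from pairing; a
patient with two organoid samples at the same timepoint is an error
requiring disambiguation rather than silent averaging.

*Expression-derived copy number.* A deliberate simplification of
HMM-based inference: per gene, log2 expression minus the mean log2 of ≥ 3
reference samples, winsorized to ±3; per chromosome, a centered moving
average (window 101 genes, edges truncated); a chromosome is called
loss/gain when its mean ratio crosses ∓0.15. There is no HMM, no
subclustering and no segment-level calling — the profiler is designed to
recover arm/chromosome-level events (e.g. the chr9/chr10 losses typical of
melanoma), not focal amplifications. Because a ~50-gene chromosome mean has
substantial sampling noise, the copy-number test fixtures generate cohorts
with reduced biological variation (patient effect and tissue noise SD 0.2,
no planted tissue programs) and metastasis-only reference panels, so that
a planted one-copy loss (log2 ratio −1) dominates everything else; under
those conditions the planted chr9/chr10 loss is called exactly.

## Signature discovery

Per patient with exactly one baseline and one stimulated culture, the fold
change is log2((stim + 1)/(base + 1)) on raw abundances — the +1
pseudocount is robust to zeros and scale-free for the selection rule. A
gene is a candidate iff (i) mean responder lfc ≥ 1.0, (ii) lfc > 0 in
≥ 75% of responder patients, (iii) mean non-responder lfc < 0.5. The
thresholds are parameters (`DiscoveryParams`); they were chosen so that on
the default synthetic cohort the selection behaves like the intended
biology — a clear responder-specific program with few passengers. There is
no p-value machinery and no multiple-testing correction: with 4 + 4
patients the selection is effect-size- and consistency-based by design.
Selection is monotone in its thresholds and order-independent.

The exclusivity filter keeps a candidate iff its detection fraction
(count > 0) is ≥ 0.10 across T cells and ≤ 0.02 in every other cell type.
Detection fractions, not mean expression, make the rule robust to a few
high-count outlier cells. Both T-cell labels (`T_cell`, `CD8_T`) count as
T cells.

## Scoring, deltas, survival

Pre/on-treatment deltas are per-patient (on − pre) composite scores;
patients with stable disease, partial or complete response form the
benefit group and progressive disease the no-benefit group; groups are
compared by a two-sided rank-sum test (skipped with a warning when only
one group has pairs). Tertiles are rank-based with remainders assigned
low-first and ties broken by patient id — determinism over aesthetics.
Survival uses the product-limit estimator per tertile and the k-group
log-rank test (k−1 df), plus the pairwise high-vs-low log-rank. The
log-rank implementation is cross-checked in the test suite against an
independent brute-force risk-set computation on exhaustively generated
small datasets. No Cox modeling or covariate adjustment is provided: the
intended analysis is unadjusted tertile stratification.

## Spatial rules

The classification rules are parameter-free restatements of the intended
definitions: MHC-I high iff log2(B2M count + 1) ≥ 3 (boundary inclusive, so
a count of 7 → log2 8 = 3 → high; threshold and log base configurable);
melanin low iff all four of MITF, TYR, MLANA, PMEL are exactly zero — raw
count zero is the only parameter-free reading of "no expression". The CD8
checkpoint score is the mean of log2(count+1) over PDCD1, LAG3, TIGIT and
HAVCR2 — a mean rather than per-cell z-scores because z-scoring a sparse
4-gene panel at n = 20 cells is unstable. Immune cells for proximity are
T_cell, CD8_T, B_cell and myeloid; nearest distances use a k-d tree,
verified against an all-pairs computation in tests.

## TCR repertoire statistics

"Specific clones" are clonotypes with count ≥ `min_count` (default 2) —
the recurrent/singleton boundary; the choice is exposed and logged.
Diversity: Shannon entropy in nats, normalized Shannon (entropy / ln
richness, defined 0 for single-clone repertoires), inverse Simpson. All
are permutation- and scale-invariant. The clonality–expression coupling is
the Spearman correlation between per-sample specific-clone counts and the
T-cell population score.

## The synthetic cohort generator

One root seed; each modality draws from its own fixed sub-stream, so
modalities regenerate independently and all outputs are bit-reproducible.

*Bulk* (default 8 patients, half responders, 2,000 genes): log2 expression
= gene baseline N(3, 1.5) + patient effect N(0, 1.2) + tissue noise
N(0, 0.4) + residual N(0, 0.2), exported as 2^x − 1 floored at 0
(FPKM-like). Stimulated responder cultures add a log2 FC of 2.0 on the
14 signature genes. Metastases add +1.0 on stromal/monocytic markers
(culture depletes stroma); organoid samples shift T-cell markers by the
patient's latent T-cell level (lognormal, SD 0.7 on the log scale), the
same level that scales that patient's clone-pool size — this is what
couples clonality to expression. The residual SD of 0.2 was set below the
tissue noise on the reasoning that technical replication error is smaller
than metastasis-to-culture drift.

*Single cell* (default 300 cells × 6 types): negative-binomial counts;
signature genes detected in ~2/3 of T cells and leaking into other types
with probability 0.005; canonical markers enriched in their own
compartment; housekeeping genes broad.

*Clones*: per-patient clonotype pool (~200 × T-cell level), counts i.i.d.
zipf(2.5) per timepoint; stimulated responder samples multiply 15
uniformly chosen clonotypes by 5. Expansion acts on a random subset —
including singletons — because promoting rare clones to recurrent ones is
both the biology of antigen-specific expansion and the only mechanism that
changes the specific-clone count; expanding only the already-largest
clones would not.

*Spatial*: immune cells in Gaussian clusters; responder-arm tumor B2M is
Poisson with mean 40·exp(−d/75 µm) of the nearest immune cell; the
resistant arm has mean 0.2 B2M, melanin zero-inflation 0.7 vs 0.1, and CD8
checkpoint means 0.05 vs 4.0. CD8 pool sizes default to 261 (responder)
and 20 (resistant), the sizes of the two profiled lesions.

*Validation* (default 300 patients): each patient has a latent score
u ~ N(0,1); signature genes shift by 2.0·u in both samples (so the
measured composite tertile recovers the planted tertile in ≥ 90% of
patients — the generator's prescribed calibration), responders add the
activation program on-treatment. Survival is exponential with per-tertile
hazard 0.06/month (low), ×√0.4 (mid), ×0.4 (high), censored uniformly on
[0, 60] months.

What the generator does **not** emulate: read-level data, batch and
chemistry effects, gene–gene correlation structure, realistic dropout
curves, the real external cohorts' distributions, or subclonal
heterogeneity. Passing tests therefore demonstrate that the statistics
recover planted effects of plausible magnitude under idealized noise —
they do not certify performance on real cohorts.

## Problem sizes and numerical choices

The acceptance suite runs the sizes the analyses are designed for: 20
simulated discovery cohorts (plus 20 planted-null cohorts), 50-seed
permutation and hazard-ratio-1 calibrations, survival power at n = 300,
pre/on deltas at n = 42, spatial arms at 261/20 CD8 cells. Unit tests use
smaller cohorts (120 genes, fewer cells) where only structure, not power,
is under test. Ties in rank statistics use midranks throughout (scipy
defaults); tertile ties break by patient id; percentage rounding is half
away from zero to match clinical-table conventions (22/31 → 71%,
11/14 → 79%).

## Known limitations

- The discovery thresholds are calibrated to small paired cohorts
  (~4 + 4 patients); with many patients a test-based selection would be
  more appropriate.
- The copy-number profiler is chromosome-level only and assumes the
  reference panel shares the cohort's expression baseline.
- Composite scores are cohort-relative; applying a signature to a cohort
  of one is undefined and to very small cohorts unstable.
- The spatial rules assume segmented, typed cells with panel counts as
  input; no segmentation or decoding is performed.
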