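# Methods

## Problem and model

The package targets a small-cohort clinical prediction problem: after
splenectomy with cardia devascularization for cirrhotic portal
hypertension, which of the recorded clinical indexes carry risk for
portal vein system thrombosis (PVST), and how well can an SVM built on
those indexes predict it? The reference cohort shape is 92 patients
(52 PVST, 40 non-PVST) with 33 indexes: six countable indicators (age,
gender, weight, bleeding volume and two antithrombotic therapy flags)
and 27 repeatedly measured lab values, each collapsed to the
per-patient median of its post-operative recordings.

### Preprocessing

Indexes are measured on wildly different scales, so every column is
first min-max normalized to [0, 1] and then coded into {−1, 0, 1}
against the mean μ_j ± standard deviation σ_j of the normalized column
(strict inequalities; the boundaries fall in the 0 band). The chain is
scale-equivariant: any a·x+b transform with a > 0 leaves the output
unchanged. Statistics are fitted on training rows only and applied to
held-out rows, clipping normalized test values into [0, 1]; this
per-fold fitting is a deliberate leakage-control choice (the standard
cross-validation hygiene) where the protocol is otherwise silent.
σ uses the sample convention (n−1), configurable via `ddof`. Missing
values raise by default; per-feature median imputation is available
behind `missing="median"` because silent imputation hides data
problems. Boolean indexes pass through the same chain without
exemption.

By default the discretized matrix feeds scoring, correlation and the
SVM alike (`representation="discretized"`); the normalized-only
representation is available as a switch since the processing chain
admits either reading.

### Scoring

Discernibility is the extreme cross-class pair count
dis_j = max{N₀N₁ − S(j), S(j)} with S(j) the number of ordered
(non-PVST, PVST) pairs whose difference is ≤ 0. It is a rank statistic
(invariant to strictly increasing transforms) and direction-free.
The literal "≤" counts tied pairs fully; this is the default
(`tie_mode="paper"`) and has a documented pathology: a constant column
ties every pair and scores the maximal dis = N₀N₁. `tie_mode="midrank"`
counts ties ½, recovering the classical Mann–Whitney statistic and
neutralizing the pathology, at the cost of deviating from the literal
definition. Fidelity first, robustness available.

Independence is ind_j = exp(−pr) with pr an absolute Pearson
correlation. Features at the global dis maximum (ties included — the
"strictly higher discernibility" set would be empty for them) pair with
their least-correlated partner, guaranteeing the top feature the
highest achievable independence; all others pair with their most
correlated strictly-stronger partner, so a feature shadowed by a
correlated stronger one is discounted. A constant vector's correlation
is defined as 0 (maximally uninformative) with a warning, avoiding 0/0.

Risk degree RD_j = dis_j · ind_j ranks the features (ties broken by
descending dis, then ascending feature id — deterministic). The risk
set is the ranking prefix before the largest RD drop, searched over cut
positions 1 … n−1 (earliest position on gap ties; top-1 with a warning
if all RD are equal). A fixed set size can override the automatic cut
(`n_select`). The largest-gap rule is this package's concrete reading
of "indexes with much higher risk degree than the rest"; the original
procedure's exact cut is not specified anywhere, and reported per-fold
set sizes (2–8) show it is data-driven.

### Prediction and evaluation

The classifier is a soft-margin SVM (established solver; no
reimplementation) with RBF kernel exp(−γ‖x−x′‖²); γ plays the role of
1/σ² in the kernel's textbook form. (C, γ) are tuned by exhaustive grid
search over powers of two 2⁻⁷ … 2⁷ — a span covering every tuned pair
observed in the reference experiments — scored by stratified 5-fold
inner cross-validation accuracy on the training part, ties resolved
toward the smallest C then smallest γ (least complex model; value-based,
hence invariant to grid enumeration order). Predicted label = sign of
the decision value, an exact 0 mapping to +1.

Nine confusion-matrix metrics are computed exactly as defined, with the
complements FPR = 1 − specificity, FNR = 1 − sensitivity,
FDR = 1 − precision holding identically. AUC uses the rank-sum form
(R₊ − n₀(n₀+1)/2)/(n₀n₁) with ascending mid-ranks over the decision
values; as printed, the defining sum runs over all patients (a
constant), so it is resolved to the sum over positive-class ranks —
the only reading matching the n₀(n₀+1)/2 offset and giving a perfect
ranking AUC 1. Decision values rather than calibrated probabilities
feed the ranking; AUC only needs ranks, so the distinction is
immaterial. Degenerate 0/0 cells: precision/FDR with no predicted
positives are NaN and propagate through averages (matching how such
cells are conventionally reported); MCC with a zero marginal is 0,
flagged.

### Cross-validation protocol

Outer 5-fold stratification deals a seeded per-class shuffle
round-robin, so per-fold class counts differ by at most one (52/40 over
5 folds: 10–11 positives and exactly 8 negatives per fold). Per fold,
preprocessing and selection are fitted on the training part only — a
mutation test perturbing held-out rows verifies that the selected set
and tuned hyperparameters never change. Models are evaluated for a
ladder of ranking-prefix sizes, 1, 1+step, … up to the detected set
size plus the detected size itself (default step 2), mirroring the
several-models-per-fold reporting structure. The aggregate is the
unweighted arithmetic mean over all evaluated rows (not per-fold best);
this convention is pinned by a transcribed 13-row benchmark table whose
printed Average row it reproduces at 2-decimal rounding in every
column. The default outer seed is 20191230, configurable.

### Significance testing

Selectors are compared over blocks — one block per (fold, subset-size)
model, one metric at a time. Friedman's χ² uses within-block mid-ranks
with the standard tie correction (ties are common when accuracies
coincide), df = k−1, upper-tail χ² p-value. The post hoc is a
Nemenyi-type multiple comparison: pairwise mean-rank differences
against CD = q_{α,k}/√2 · √(k(k+1)/(6N)) with the studentized-range
quantile at the stated confidence — the standard companion of Friedman
over algorithms, chosen because the original procedure names only "a
multiple comparison test". S-weight and LLEScore comparisons are not
reimplemented (their definitions live outside the source material);
the selector registry accepts plugins so a wider comparison can be
reconstituted.

### Baseline selectors

* **Relief** (classic binary form): over n_samples seeded-shuffled
  instances (default: each instance once), weights update by the
  Manhattan-distance nearest hit and miss on range-normalized features.
* **SVM-RFE**: recursive elimination on linear-SVM |w|, one feature per
  round, ranking = reverse elimination order; cross-checked in tests
  against an established RFE implementation.
* **mRMR** (difference scheme): greedy maximization of
  I(f; y) − mean_{g chosen} I(f; g), empirical mutual information in
  nats, zero-probability cells contributing 0.

Original-publication parameter choices for these baselines are not
derivable here; the defaults above are documented package choices.

## Synthetic cohort generator

`paper_like_spec()` emulates the reference cohort's structure at its
scale: 52/40 patients, 33 features; two boolean "therapy" indicators
with strong class association (Bernoulli rates σ(±β/2) with log-odds
separation β = 3, i.e. ≈ 0.82 vs 0.18, odds ratio ≈ 20); three moderate
continuous lab signals (unit-variance Gaussians with standardized
class mean-shift δ = 0.5); five redundant copies at ρ = 0.8
(ρ·standardized source + √(1−ρ²)·noise); the rest independent Gaussian
noise. β and δ were calibrated once so the generated discernibility
structure matches the intended ordering — boolean indicators clearly
strongest (mean dis fraction ≈ 0.97 of N₀N₁), continuous signals
intermediate (≈ 0.85), noise below — because the tie-inclusive pair
count otherwise lets discretized continuous features overtake the
boolean indicators (at δ = 1 they reach ≈ 0.93 and occasionally take
the global maximum). All randomness flows from one seed through a
per-feature split of the seed sequence, so draws are independent of
generation order. `generate_longitudinal` expands measurable indexes
into dated per-visit records built from antisymmetric noise pairs, so
the per-patient median recovers the latent value exactly for odd visit
counts.

What the generator does **not** emulate: real lab marginals (reference
ranges, skew, detection limits), within-class dependence between the
two therapy indicators (they are independent given the label, which
*forces* their marginal correlation to ≈ 0.36 at β = 3), measurement
drift over visits, or missingness. Passing recovery tests therefore
show the pipeline recovers signals under this idealized structure, not
that it would rank real clinical indexes the same way.

## Known limitations

* **Tie inflation.** With the literal tie counting, heavily tied
  columns (booleans, three-level discretized features, constants) have
  systematically inflated dis; a constant column attains the maximum.
  Mid-rank mode is provided as the principled alternative. Relatedly,
  a near-balanced boolean column can collapse to all-zeros under the
  ±σ discretization band (σ of a balanced 0/1 column is ≈ 0.5, so both
  levels land inside the band), after which the tie pathology awards it
  maximal dis.
* **Second-strong-feature discount.** The independence definition
  anchors every non-maximal feature to its most correlated stronger
  feature. Two strongly class-associated indicators are necessarily
  mutually correlated under a label-driven generative model, so the
  runner-up is discounted (ind ≈ e^{−0.36} ≈ 0.70 at β = 3) while the
  top feature keeps ind ≈ 1; the largest-gap cut then typically selects
  a single feature (measured mean detected-set size ≈ 1.1 on the
  preset, and both therapy indicators land inside the detected set in
  only ≈ 11% of seeds — reported as-is by the acceptance script and the
  corresponding acceptance test, which fails by design rather than
  masking the behavior). Recovering multi-feature risk sets of the kind
  reported on the original cohort appears to require strong features
  whose mutual correlation is far lower than this generative model can
  produce.
* **Problem sizes.** Oracle sweeps run at m ≤ 20, n ≤ 6 (500 cohorts),
  AUC checks at m ≤ 15 (500 vectors), Friedman cross-checks on 100
  random matrices, and recovery studies at the full 92 × 33 preset
  scale over 200/100 seeds — sizes chosen to exercise every code path
  while keeping the default suite quick.
* No imaging/free-text/time-series modelling beyond the median; no ROC
  curves, probability calibration, or confidence intervals on metrics.
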