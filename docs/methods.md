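# Methods

## The model

`connectrl` treats a resting-state functional brain network as a
discrete-time linear time-invariant (LTI) system

    x(t+1) = A x(t) + B u(t)

where `x(t)` is the vector of regional activity, `A` is derived from the
subject's functional-connectivity (FC) matrix, and `u(t)` is an external
control signal injected through the input matrix `B`. For a single control
region κ, `B` is the indicator vector `b_κ` and the controllability Gramian

    W_κ = Σ_{τ≥0} A^τ b_κ b_κᵀ (Aᵀ)^τ

converges iff `A` is Schur stable; it is the unique solution of the
discrete Lyapunov equation `W = A W Aᵀ + b_κ b_κᵀ`. **Average
controllability** of region κ is `trace(W_κ)` — the established scalar
operationalization of how strongly low-energy input at κ can drive the
network into nearby states. The τ = 0 term contributes exactly 1, so every
value is ≥ 1; values on stabilized correlation matrices land in a narrow
band just above 1 (≈ 1.0–1.2 in practice).

### From correlations to a stable system

FC is the Pearson correlation of ROI time series, diagonal zeroed
(self-coupling excluded — the standard connectome convention), negative
weights retained as signed couplings by default (an absolute-value mode is
available via `absolute_fc` since the literature is split on sign
handling). No Fisher z-transform is applied. Stability is enforced by the
standard normalization

    A = FC / (c + σ_max(FC)),  c = 1 (default),

which bounds the largest singular value by σ_max/(1+σ_max) < 1 for any
input, symmetric or not.

### Numerical route

For symmetric `A = V diag(λ) Vᵀ` the whole profile follows from one
eigendecomposition:

    trace(W_κ) = Σ_i V[κ,i]² / (1 − λ_i²),

which replaces 90 Lyapunov solves per subject with one `eigh`. Non-symmetric
matrices fall back to per-node `scipy.linalg.solve_discrete_lyapunov`. Both
routes are cross-checked in the tests against a third, independent one —
direct evaluation of the truncated series — to 1e-8, with the number of
terms chosen so the neglected tail is below 1e-12. Gramians are symmetrized
after the solve; residual tolerance is 1e-8 and the PSD tolerance 1e-10.

### Band-pass filtering

The optional temporal filter is a zero-phase (forward–backward) Butterworth
band-pass of order 2 with the conventional resting-state band
0.01–0.08 Hz. Only the band is a domain constant; the filter family and
order are implementation choices (documented here, configurable). The
filter defaults to off for synthetic cohorts because the generator already
controls the spectrum through its AR(1) coefficient.

## Group statistics

Per region: group means, difference (group A − group B), two-sample t-test
(Student's pooled-variance, df = n_a + n_b − 2, two-sided; Welch available
via `equal_var: false`), Mann–Whitney U (midrank ties; asymptotic two-sided
p with tie and continuity correction — exact enumeration is unnecessary at
cohort sizes of ~130/156, and the U statistic itself is verified against
brute-force pair counting in the tests), and Benjamini–Hochberg adjusted
p-values computed across all regions' t-test p-values. Top-k rankings break
ties by ascending atlas ID. All tests are two-sided.

## Classifier evaluation

Features are the average-controllability values of regions with t-test
p < α (default 0.05), ordered by atlas ID; an explicit region list can
override the selection. The classifier is a fully connected network —
input → six ReLU hidden layers of 64 units → sigmoid output — with
inverted dropout (rate 0.25) after every hidden layer during training
only. Depth, dropout rate and the output nonlinearity are the evaluated
design; the width (64), optimizer (Adam, lr 1e-3), 200 epochs and batch
size 32 are free choices sized to the small feature count, all
configurable. The implementation is a compact NumPy forward/backward pass,
fully deterministic under a seed.

Evaluation is stratified k-fold cross-validation (default k = 10): classes
are shuffled and dealt round-robin onto folds with a continuing pointer, so
per-fold class counts and fold sizes each deviate by at most one subject
from an even split (this dealing remains well-defined down to the
leave-one-out limit k = n). Features are z-scored with training-fold
statistics only. The held-out fold is scored at threshold 0.5 into a
confusion matrix (true × predicted, pooled across folds); ROC points come
from the threshold sweep over distinct scores and AUC from the trapezoidal
rule, which the tests pin to the Mann–Whitney concordance probability to
1e-10. Both pooled and fold-averaged accuracy are reported since either
convention appears in practice.

## The synthetic cohort generator

No clinical cohort ships with the package, so a seeded generator emulates
the study design the pipeline targets: two groups of 130 (label 0) and 156
(label 1) subjects, 90 AAL regions, 950 timepoints at TR = 0.5 s.

Generative model, per subject:

1. **Ground-truth network** — modular symmetric coupling matrix: 6
   contiguous modules, within-module weight 0.3, between-module weight
   0.05, Gaussian edge jitter sd 0.05. Modularity and these magnitudes give
   FC values in the range typical of empirical resting-state correlation
   matrices (within-community r ≈ 0.3–0.5, weak background).
2. **Group effect** — in group B every coupling incident to one of the 8
   designated effect regions (atlas IDs 33, 40, 59, 69, 70, 77, 78, 90) is
   scaled by `effect_multiplier` (default 0.85). A multiplier < 1 weakens
   those regions' couplings and lowers their average controllability, so
   the group-A-minus-group-B difference at effect regions is positive. The
   multiplier is a calibration knob, not an empirical quantity.
3. **Subject covariance** — subject coupling = group network + symmetric
   Gaussian jitter (sd 0.02), then Σ = coupling + λI with
   λ = max(0, 0.1 − λ_min(coupling)): the minimal positive-definite lift
   that preserves relative coupling structure.
4. **Time series** — rows drawn i.i.d. from N(0, Σ), smoothed with an
   AR(1) filter (coefficient 0.3, mimicking BOLD temporal smoothness
   without modeling hemodynamics), plus white observation noise (sd 0.3).

Per-subject seeds derive from the cohort seed via a splitmix64-style
integer mix of (seed, group, subject index), so cohorts are bit-identical
across runs and per-subject streams are independent of generation order.

**What the generator does not emulate:** hemodynamic response functions,
voxel-level spatial structure, head motion and scanner artifacts, global
signal, anatomical heterogeneity of module boundaries, and any empirical
effect size — the injected effect is far cleaner than clinical group
differences. Passing tests therefore demonstrate correctness and
calibration of the pipeline, not that the classifier's synthetic-data
performance transfers to real cohorts.

## Calibration properties the suite enforces

- Null cohorts (multiplier 1): per-region t-test rejections at α = 0.05
  stay inside the Binomial(90, 0.05) 99% interval, and cross-validated
  accuracy and AUC stay inside [0.40, 0.60].
- Effect cohorts (multiplier 0.85): the 8 smallest t-test p-values recover
  at least 6 of the 8 injected regions; at multiplier 0.7 the mean
  cross-validated AUC exceeds 0.7.
- All average-controllability values across the full 286 × 90 cohort
  respect the ≥ 1 lower bound.

These checks run at the full study scale (286 subjects, 90 regions, 950
timepoints), which the eigendecomposition route makes cheap (a few seconds
per cohort).

## Degenerate inputs and tie-breaks

Zero-variance regions abort FC computation with the region named; series
shorter than the zero-phase filter's padding requirement are rejected;
non-stable systems (σ_max ≥ 1) are refused by the Gramian solver; an empty
significant-region set raises with a suggestion to pass an explicit region
list; manifests mixing time-series and matrix files, duplicating subject
IDs, or carrying labels outside {0, 1} are rejected with the offending
entry named. Top-k ties break by ascending atlas ID; fold dealing breaks
ties by the seeded shuffle.

## Known limitations

- The discrete-time formulation is implemented throughout; a
  continuous-time Gramian variant is not provided.
- Modal controllability, control-energy trajectories and structural (DTI)
  networks are out of scope.
- No covariate adjustment (age/sex), cluster correction or effect-size
  confidence intervals in the group statistics.
- No hyperparameter search for the classifier; the single fixed
  architecture is evaluated as-is.
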