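# Methods

## Generative model of the synthetic spectra

Each synthetic sample i is drawn as

    A_i(λ) = s_i · [ l · SSC_i · ε(λ) + b_i + d_i(λ) ] + e_i(λ)

with SSC_i ~ Normal(ssc_mean, ssc_sd) truncated to [8, 18) °Brix (rejection
sampling with a retry cap), flat baseline b_i ~ Normal(0, baseline_sd),
multiplicative scatter s_i ~ Normal(1, scatter_sd) applied to signal plus
baseline (the classic scatter-correction target), i.i.d. photometric noise
e ~ Normal(0, noise_sd), and ε(λ) a mixture of Gaussian absorption bands.
d_i(λ) is an optional smooth per-sample baseline drift: white noise
convolved with a Gaussian kernel of correlation length `drift_length_nm`,
rescaled to pointwise sd `drift_sd`. It models wavelength-dependent stray
light and scattering and is off by default, leaving the pure
Lambert–Beer-plus-flat-baseline model.

Defaults and why:

- `ssc_mean = 12.63`, `ssc_sd = 1.78` °Brix solve P(SSC ≥ 14) = 0.22 and
  P(SSC < 10) = 0.07 for the untruncated normal, so the default grading
  scheme yields ≈ 22/71/7 grade proportions per 100 samples — the cohort
  composition the pipeline's class-balancing stage is sized for.
- Bands at 461, 469 and 750 nm (characteristic carbohydrate absorption
  wavelengths in the visible range), width 30 nm — visible absorption bands
  of sugars/pigments are tens of nm wide and a Gaussian profile is the
  standard surrogate when no measured band shape exists.
- Band strengths (0.04, 0.04, 0.025) absorbance per °Brix per unit path put
  peak absorbance near 1 AU for mid-grade fruit, a realistic operating
  point for a 10 mm cuvette.
- Corruption defaults are 0: the base generator is the exact linear model,
  so tests can assert machine-precision recovery. The canned fixtures turn
  defects on: `noisy` (noise_sd 0.01), `scattered` (noise 0.002 — the
  typical photometric accuracy of a benchtop UV-Vis instrument — flat
  baseline 0.05, scatter 0.05, drift 0.1 with 100 nm correlation length,
  i.e. drift comparable to 10 % of peak absorbance).
- Fixtures (n ≤ 40) use a wider SSC population (mean 12.5, sd 2.5) so all
  three grades contain enough samples to stratify and oversample at small n.

What the generator does **not** emulate: instrument response functions,
detector nonlinearity, temperature effects, band-shape changes with
composition, and any nonlinearity of absorbance in SSC. The last point
matters when reading test results: because the true feature→SSC map is
linear, a full-rank linear calibration (PLS1/OLS) is near-optimal on this
data and exact when corruption is off. Passing tests therefore demonstrate
that each stage does its job and that the hybrid optimizer improves the
network it optimizes — they do not demonstrate that the network beats a
linear baseline, which on real fruit spectra rests on nonlinearities this
generator deliberately omits.

## Grading scheme

Grades are half-open °Brix intervals — Grade 1 [14, 18), Grade 2 [10, 14),
Grade 3 [8, 10) — so every value in [8, 18) has exactly one grade and
boundary values like 13.995 stay in the lower-quality grade. SSC outside
the scheme raises an error rather than clamping; synthetic parameter sweeps
would otherwise be silently corrupted.

## Pretreatment operators

SNV uses the sample (n−1) standard deviation. Derivatives are plain finite
differences on the uniform 5 nm grid (central differences inside, one-sided
at the two endpoints), not SG-derivatives: the pipeline treats SG smoothing
and differentiation as separate operators and composes them explicitly as
SD–SG (derivative first, then smoothing; the reverse order is available as
a sensitivity toggle). SG smoothing uses least-squares polynomial
convolution with one-sided polynomial fits at the edges so that every
operator preserves the 81-point grid. SG defaults (window 7, polyorder 3)
are conventional choices; both are exposed in the config.

A structural note on SNV/VN: for a fixed-shape single-component spectrum,
per-spectrum normalization removes the concentration information along with
the scatter. On synthetic data these methods therefore grade near chance —
an expected property of the generative model, not a defect of the
operators.

## PCA and latent-variable selection

Columns are mean-centered, never variance-scaled (the contribution rates
are defined on covariance eigenvalues, and per-spectrum scaling is the
pretreatment stage's job). The eigendecomposition uses the symmetric solver
on the explicit covariance matrix; loading signs are fixed by making each
column's largest-magnitude element positive. k is the smallest integer with
cumulative contribution Φ_k ≥ threshold (default 0.99 in the pipeline, with
0.95 and a manual override available). In split-first protocols the PCA is
fit on the training portion only and test spectra are projected with the
training model.

## SMOTE

Per class with multiplier f, each original row parents exactly f−1
synthetic rows, each interpolated toward one of its k nearest same-class
neighbors (k auto-reduced to class size − 1). Class counts scale exactly;
originals pass through bit-identical; synthetic rows never leave the class
convex hull. For regression the °Brix target is interpolated with the same
u as the features. Defaults (multipliers 3/1/4 for grades 1/2/3, k = 5)
map the 22/71/7 cohort to 66/71/28.

## Network and training

Three layers; logistic sigmoid hidden activation; sigmoid outputs with
one-hot targets for grading (argmax prediction, ties to the better grade),
linear output for regression. Hidden size follows h = round(√(m+n)) + a
with a ∈ [1, 10]; a = 8 gives the 14-neuron classification net at 35
inputs, a = 4 the 10-neuron regression net. Weights start uniform on
[−0.5, 0.5], thresholds at zero.

Training is full-batch gradient descent on the classic batch error
E = ½ Σ (y − t)² (the delta rule; traces report MSE for comparability).
Under this convention the conventional initial rate η₀ = 0.001 trains a
standardized-input network in 1–2 thousand epochs; with a mean-MSE
gradient the same printed rate would be two orders of magnitude too small.
Inputs (PCA scores) are standardized to zero mean and unit variance on the
training split; regression targets are standardized internally and
predictions mapped back to °Brix.

The four decay schedules are evaluated at the epoch index; defaults
γ = T/3 (gaussian) and γ = 10/T (sigmoid), p = 2 (exponential). The sigmoid
schedule's sign is chosen so that it decays — the textbook logistic form
increases with t. All schedules are non-increasing on [0, T]; gaussian and
cosine start exactly at η₀ and cosine ends exactly at 0.

A limitation found while validating: the folk claim that a decaying rate
reaches a *lower final training MSE* than the same fixed rate does not hold
on this package's synthetic losses at any stable rate — fixed-rate descent
simply trains longer at full strength on these smooth objectives, and at
unstable rates both runs saturate because the decayed schedule still starts
at η₀. The schedules are therefore tested against their closed forms and
monotonicity, not against a training-MSE superiority claim.

## PSO hybrid

Canonical inertia-weight PSO, per-dimension uniform random factors,
velocities clamped to half the box width, positions clipped to the
symmetric box ([−2, 2] per weight by default), N = 30 particles. Fitness is
training-set MSE of the decoded network only — test data never enters the
optimizer. The published parameter sets are the defaults: ω = 0.2,
c₁ = 1.4, c₂ = 2 with 100 iterations for grading; ω = 0.7, c₁ = 1.9,
c₂ = 1.7 with 400 iterations for regression. After PSO the best particle is
refined by schedule-driven gradient descent (a PSO-only mode is available
by setting gd_epochs = 0). The global-best fitness is non-increasing by
construction and is asserted on every run.

In high-dimensional score spaces (many latent variables on noisy data) the
global search can reduce training error at the cost of hold-out error;
on low-dimensional problems (clean data, few LVs) it reliably improves the
refined network. The pretreatment comparison therefore uses the plain
gradient-descent classifier, which is also what a per-method comparison
table measures.

## PLS1 baseline

NIPALS with X-deflation, single response; coefficients
B = W (PᵀW)⁻¹ q (pseudo-inverse guards rank exhaustion). With full
components it reproduces OLS, which the tests assert against the
normal-equations oracle. It consumes the same PCA scores as the network, so
the comparison isolates the regressor.

## Split protocols

Two orderings exist for combining augmentation with the 8:2 stratified
hold-out and both are supported: `augment-first` (augment the whole score
table, then split — the qualitative default, giving 165 → 132/33) and
`split-first` (hold out raw samples untouched, augment the training part
only — the quantitative default, which is leak-free and is the protocol the
leakage test asserts: perturbing hold-out spectra changes no fitted
statistic). Per-grade test counts are nearest-integer rounded with the
remainder absorbed by the largest grade.

## Metrics conventions

Accuracy is percent correct; recall and F1 are macro-averaged over grades
(micro-F1 would equal accuracy, which a separately-reported F1 contradicts);
an unpredicted grade contributes F1 = 0. ROC AUC is one-vs-rest on the raw
sigmoid outputs, computed by midrank (Mann–Whitney) statistics, equivalent
to trapezoidal integration over all thresholds. All dispersion statistics
use the sample (n−1) variance, under which SE = sd/√n and CV = sd/mean
reproduce published per-grade tables to their printed precision (CV is a
fraction, not percent). RMSECV is leave-one-out by default with a
contiguous k-fold fallback for expensive models.

## Problem sizes

Default study sizes are a 100-sample cohort (the cohort size the grade
proportions are calibrated to) and 40-sample fixtures for per-stage tests;
classification trains 1800 epochs (T = 1800) and regression 2000, with PSO
budgets of 100/400 iterations as above. These sizes make the full test
suite and the acceptance script each run in well under a minute on one CPU
while leaving every stage's behaviour measurable.
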