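# Methods

This note records the modelling assumptions, numerical choices and known
limitations behind `tojcortex`. It complements the API documentation: the
README says what the package does, this file says why it does it that way.

## Psychometric models

**Uncrossed condition.** The probability of judging the left hand as
stimulated second is modelled as a cumulative-Gaussian sigmoid with four
free parameters: upper and lower asymptotes P_max, P_min (lapse/guess
levels), width σ_u (ms) and horizontal shift d_u (ms). The sign convention:
negative SOA means the left hand was stimulated first.

**Crossed condition.** The crossed curve mixes the subject's uncrossed
sigmoid with two Gaussian "flips" that share a width σ_f and centre d. The
peaks A_l, A_r ∈ [0, 1] and the constant offset c ∈ [0, 1] control how much
of the sigmoid is inverted: A = 0, c = 0 leaves it untouched; c = 1 inverts
it completely; intermediate values produce the characteristic N-shaped
profile. The crossed fit holds the sigmoid at the subject's uncrossed
maximum-likelihood estimate rather than refitting jointly — the crossed
model is defined *in terms of* the uncrossed curve, and the two sessions
are separate experiments. The model evaluation is clipped to [0, 1];
whether the original optimisation allowed transient excursions outside the
unit interval is unknowable from the published description, and clipping is
the conservative choice.

**Fitting.** Both models maximise the binomial log-likelihood of the
per-SOA counts, with probabilities clipped to [1e-6, 1 − 1e-6]. The flip
likelihood is multimodal (a narrow high flip and a wide low flip can
produce similar curves), so the optimiser runs 20 L-BFGS-B starts from a
Latin-hypercube over the box constraints (A, c ∈ [0,1]; σ_f ∈ [1, 1500] ms;
d ∈ [−900, 900] ms; σ_u ∈ [1, 600] ms; d_u ∈ [−300, 300] ms) and keeps the
best. The asymptote ordering P_min ≤ P_max is enforced with a smooth
penalty rather than a reparametrisation, keeping the parameter meanings
direct.

**Goodness of fit.** Pearson chi-square with the per-level binomial
variance, χ² = Σ (k − n·p)² / (n·p·(1−p)), and df = n_levels − n_params − 1
(12 − 4 − 1 = 7 uncrossed; 14 − 5 − 1 = 8 crossed). A fit is accepted when
P > 0.05, or — the fallback used when sampling noise trips the test on an
otherwise adequate curve — when the determination coefficient of observed
vs predicted per-SOA frequencies exceeds 0.4.

**Reversal value.** ∫|P_c − P_u| dSOA over [−900, +900] ms (trapezoid rule,
default 1 ms grid), divided by the 1800 ms domain width, its maximum
possible value: 1 means complete reversal at every SOA. The domain is the
crossed design's span; the uncrossed curve is model-extrapolated beyond its
±300 ms sampling range, which is safe because the sigmoid is asymptotically
flat there. A 5 ms grid already agrees with a 0.1 ms grid to ~1e-4.

## Cortical morphometry

Inputs are flat per-vertex tables (thickness mm, vertex area mm² — one
third of the surrounding triangle areas — and mean curvature mm⁻¹, the
average of the two principal curvatures). Per region: MCT = mean thickness;
RSI = Σ|H|·dA, a curvature-magnitude-weighted area that emphasises
convoluted cortex and ignores flat sheets; their ratio; and volume.

Choices worth noting:

- **Volume** is defined as Σ dA·T. No closed definition of regional gray
  matter volume follows from vertex scalars alone; the thickness-weighted
  area sum is a standard proxy and is exact for a prism-like sheet.
- **Curvature smoothing** is iterative uniform neighbour averaging
  (default 10 iterations) and is *optional*: surface pipelines usually
  deliver pre-smoothed curvature, in which case the input is used as-is.
  The kernel is a stand-in for whatever the upstream pipeline used; it is a
  contraction (never expands the value range) and leaves constants fixed.
- **Scanner correction** multiplies the MCT of subjects scanned on the
  thinner-reading scanner by a factor (default 1.02, i.e. a 2% correction);
  RSI needs no correction. Tags outside the known set are rejected rather
  than silently passed through.
- Whole-brain MCT is the vertex-count-weighted mean of region MCTs, which
  is identical to the mean over all vertices; RSI and volume are additive.

## Association screen

Pearson correlation per region with a two-sided p-value from the t
transform (n − 2 df). The 68 p-values of one metric form one
Benjamini-Hochberg family (q_i = min over p_(j) ≥ p_(i) of p_(j)·m/j);
correcting per metric mirrors the way the regional tests are reported, and
whole-brain correlations are reported uncorrected, outside the family. The
sex comparison uses the two-sided Wilcoxon rank-sum test, exact for group
sizes ≤ 10 without ties, otherwise the tie-corrected normal approximation.

## Probit model and selection

The reversal value y_s ∈ [0, 1] of subject s is regressed on standardized
cortical features through a probit link:

    y_s ~ Normal( Φ(Σ_i α_i F_si + C), σ_obs )  truncated to [0, 1].

The published analysis states the link but not the observation model; a
truncated Gaussian is the simplest likelihood for a continuous bounded
outcome and integrates to one on the observable range. Priors are weakly
informative for z-scored features: Normal(0, 2.5) on coefficients and
intercept, half-Normal(0, 0.5) on σ_obs. Features are z-scored before
fitting for coefficient comparability and sampler stability; an additive
0/1 sex indicator can be toggled into any model.

**Sampler.** Adaptive random-walk Metropolis, default 4 chains × (2000
warmup + 2000 kept). The proposal is an independent Gaussian per
coordinate whose relative scales track the warmup posterior spread (rolling
200-sample window) and whose global step is tuned toward a 23% acceptance
rate every 50 iterations. Convergence is monitored by split-chain R-hat
(threshold 1.01, exposed as a flag, never silently fatal); σ_obs is sampled
on the log scale with the Jacobian included. A configuration must retain at
least 1000 kept draws in total. The simulation studies and subset searches
use a lighter 2 × (600 + 500) configuration — the minimum the draw-count
rule allows — which keeps an exhaustive search over dozens of models inside
interactive runtimes.

**PSIS-LOO.** Pointwise log-likelihoods of every kept draw feed
Pareto-smoothed importance sampling: per subject, the largest 20% of
importance ratios are replaced by expected order statistics of a
generalized Pareto distribution fitted with the Zhang–Stephens
profile-posterior quantile estimator (the shape regularised toward 0.5 with
a weak prior), and smoothed weights are truncated at the largest raw
ratio. The fitted shape k̂ flags unreliable approximations at k̂ ≥ 0.7.
LOOIC = −2·elpd_loo. The implementation is validated in the tests against
brute-force exact leave-one-out refits (n = 8) and against an independent
PSIS implementation on identical draws.

**Subset search.** Every combination of up to eight candidate features
(optionally each with and without sex) is fitted and scored; the best model
is the lowest-LOOIC model with *all* Pareto-k below 0.7. Models failing the
k rule remain in the ranking but cannot win; when no model passes, the
search reports the ranking with no winner. Candidates default to the
features flagged by the association screen.

## Synthetic data: what it emulates and what it does not

The TOJ generator reproduces the behavioural design exactly: uncrossed SOAs
±15/30/60/100/200/300 ms, crossed ±30/60/100/200/300/450/900 ms, 8
repetitions each, 16 catch trials per session at a fixed 100 ms SOA (112
and 128 trials per session). Responses are Bernoulli draws from the
subject's generating curves. Catch trials get a deterministic correct
response and never enter the fitted tables — they exist to keep the trial
accounting honest. Missed/repeated trials are not simulated: sessions are
complete by construction, and misses would not enter the per-SOA counts
anyway.

The cortical generator draws per-subject region metrics around fixed
per-region population means (MCT ≈ 2.5 ± 0.15 mm across regions, subject
sd 0.12 mm; vertex |H| ≈ 0.13 mm⁻¹; vertex area ≈ 0.6 mm², loosely
calibrated to adult surface morphometry) and then constructs vertex tables
whose aggregates reproduce the drawn values *exactly* (thickness re-centred
to the drawn MCT; areas rescaled so Σ|H|dA equals the drawn RSI) — which is
what makes the aggregation stage testable to 1e-9. The latent reversal
value is Φ(Σ α·z(F) + C) plus Gaussian noise, clipped to [0, 1] —
identical in form to the analysis model, so model selection can be
validated by planted-feature recovery. Default 60 vertices per region keeps
cohorts light; vertex counts only enter the metrics through averages and
sums, so this scale-down does not change what passing tests demonstrate.

What the generator does **not** emulate: real mesh geometry (no folding,
no spatial autocorrelation between neighbouring vertices or regions),
metric correlations across regions (regions are independent given the
population means), measurement artefacts beyond a single multiplicative
scanner bias, and any nonlinearity or interaction in the structure-
behaviour coupling beyond the probit link. Recovery on these cohorts
therefore demonstrates correctness of the estimators under the assumed
model, not robustness to the many ways real cortical data violate it.
A related caveat: clipping the latent value at the [0, 1] boundary creates
occasional exactly-0/1 outcomes that the truncated-Gaussian likelihood
treats as influential; the Pareto-k rule then correctly disqualifies some
small-cohort fits. This mimics a real feature of bounded behavioural
scores and is visible in the end-to-end run as a best-model rule that is
stricter than the raw LOOIC ranking.

## Simulation-study sizes

The validation experiments use: 400 repetitions per SOA level with 30
parametric-bootstrap refits for flip-parameter recovery; n = 200 subjects
for probit posterior recovery; n = 8 subjects for the exact leave-one-out
comparison (evenly spaced design, σ_obs = 0.25 — a regime where every
refit is stable); 10 cohorts of n = 120 with coefficients (0.9, −0.7) and
noise sd 0.05 for planted-pair selection; a subdivision-3 icosphere (642
vertices) for the RSI oracle; and a 42-subject behavioural cohort matching
the study's size for the end-to-end run. These sizes give stable
recovery statistics while keeping the full suite in the low minutes on a
single core.

## Known limitations

- The Metropolis sampler is robust but slow to mix on strongly correlated
  posteriors; R-hat is reported so callers can re-run with more iterations.
  A gradient-based sampler could be swapped in behind `fit_probit` without
  changing any interface.
- The chi-square test is approximate at 8 trials per level (expected counts
  can be small); the determination-coefficient fallback exists precisely
  for that regime.
- BH-FDR assumes independence or positive dependence across regional tests;
  cortical metrics of neighbouring regions are correlated in real data.
- `region_metrics` trusts its input columns; it does not recompute
  curvature from geometry (surface reconstruction is upstream of this
  package by design).
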