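# Methods

This note documents the statistical models implemented in `frip`, the
choices made where several defensible options existed, and what the
synthetic-data generators do and do not emulate.

## The random-predator model

A depletion trial confines one predator with `N_0` prey for `T` days
without replacing consumed prey. Under random search at rate `a` per
unit prey density and a fixed handling time `h` per capture, the
expected consumption `N_e` satisfies the implicit equation
`N_e = N_0 (1 - exp(a (N_e h - T)))`, solved explicitly with the
principal branch of the Lambert W function. Assumptions: prey do not
reproduce, recover or hide during the trial; the predator does not
satiate beyond the handling-time constraint; captures are independent
given the current density. The curve is monotone increasing in `N_0`,
`a` and `T`, decreasing in `h`, and saturates at `T/h` prey per trial —
equivalently a maximum feeding rate of `1/(T h)` per experiment or
`1/h` per day.

Numerics: the Lambert argument `a h N_0 exp(-a (T - h N_0))` overflows
double precision when `a h N_0` is large, so the implementation works
with its logarithm and switches to the asymptotic fixed-point
`w <- log x - log w` above `exp(700)`. The explicit solution closes the
implicit equation to 1e-9 across the tested parameter grid, and the
per-day consumption at `N_0 = 10^4` matches `1/h` within 2%.

## Likelihood, optimisation, uncertainty

Each trial's consumption is modelled Binomial(`N_0`, `p`) with
`p = N_e(a, h, T, N_0) / N_0` clamped to `[1e-9, 1 - 1e-9]`. The
likelihood function is not stated explicitly in most published FR
analyses; the binomial form is the natural choice for bounded counts
and makes the model-consistent simulator (below) exactly well-specified.

The likelihood is maximised over `(log a, log h)` (unconstrained,
boundary-safe) by Nelder-Mead from five deterministic starts: a
moment-style start (asymptote height gives `h`, low-density proportions
give `a`) plus four fixed jitters; the best likelihood is kept. Standard
errors come from the numerically differentiated observed information on
the natural scale; Wald `z` and two-sided normal `p` follow. Fits
flagged `converged=False` report diagnostics rather than raising.

Degenerate inputs are rejected with errors: fewer than three distinct
densities, zero total consumption, or all-or-nothing consumption in
every trial (the optimum then sits on the parameter boundary).

Trials flagged excluded (predator moulted or died) never enter any fit.
Prey found dead without signs of predation count as background
mortality: they are not consumption and are not removed from the
offered totals.

## Group comparison

Differences between predator groups are estimated with the indicator
parameterisation `a = a_base + Da I`, `h = h_base + Dh I` (`I = 1` for
comparator trials), reported as `D = base - comparator`. Because the two
datasets are disjoint, the joint maximum-likelihood solution coincides
with the two separate fits and the joint observed information is block
diagonal, so `se(D)` is the root-sum-square of the separate SEs; the
implementation exploits this identity rather than re-running a
four-parameter search. Calibration was checked by simulation: with 50
replicates per density on the nine-density design, equal-parameter
dataset pairs reject each Wald test at close to the nominal 5%.

## Bootstrap

Uncertainty bands use nonparametric row resampling (unstratified by
default, matching common FR practice; stratified-by-density available),
refitting each resample from the point estimate with a single start.
95% percentile bands of predicted consumption are taken pointwise over a
density grid. A deliberately small ensemble (n = 30 by default in the
pipeline) also summarises the maximum feeding rate as mean ± SE in both
conventions; this mean ± SE is what feeds the impact metric. Resamples
that fail to converge are counted and logged; more than 50% failures is
an error.

## Response-type classification

Proportion consumed is regressed on density (optionally + density²) with
a binomial GLM whose dispersion is estimated from the Pearson statistic
(quasibinomial), using t tests on the residual degrees of freedom at
α = 0.05. Significantly negative first-order term → Type II;
significantly positive first-order superseded by significantly negative
second-order → Type III; all other patterns are reported as
"indeterminate", never coerced.

## Predation frequency and survival

Frequencies of individuals consuming any prey are compared with Pearson
chi-square tests; the 2×2 case applies the Yates continuity correction
by default while k×2 tables are uncorrected (the conventional defaults).
Survival against controls uses the two-sided Fisher exact test
(probability-mass ordering); mortality in a treatment group is
attributed to predation only when its survival is significantly below
control.

## Abundance

Quadrat counts convert to densities as count/area (default frame
0.25 m²). Published totals are allocated to size groups by the observed
proportional size composition and enter as one pseudo-sample per
published estimate, pooled with field samples. Group comparison fits a
log-link GLM with Poisson variance and a free dispersion estimated from
Pearson residuals (quasi-Poisson): the omnibus test is the scaled
deviance-drop F statistic, and pairwise contrasts are
dispersion-adjusted Wald t tests with Holm correction. Holm replaces the
single-step Tukey HSD often used in this setting: it is conservative,
assumption-light, and needs no multivariate-t machinery; the interface
leaves room for a Tukey option later. Under simulated Poisson counts the
estimated dispersion calibrates to 1 ± 0.2.

## Relative Impact Potential

`RIP = (FR_A × N_A) / (FR_B × N_B)` with `FR` the per-day maximum
feeding rate (bootstrap mean ± SE) and `N` field abundance (mean ± SE).
Uncertainty is propagated by drawing the four inputs independently and
summarising the ratio distribution over 100,000 draws (default).

Two sampling laws are provided. The default draws each input from a
lognormal matched to its mean and SE: this guarantees positivity without
rejection and gives the ratio distribution the exact small-CV property
`E[ratio] = plug-in ratio × (1 + CV_B,FR²)(1 + CV_B,N²)`, which is the
behaviour of the established RIP uncertainty tooling this module
reproduces. A truncated-normal (rejection) law is available as an
option; at denominator CVs near 0.25 its reciprocal moments are a few
percent larger than the lognormal's, which is visible in the ratio mean.
Interval convention: the reported `q%` interval spans the `(100-q)`th to
the `q`th percentile of the draws — again the convention of the
established tooling; equal-tailed central intervals are available via
`RIPResult.central_interval`. The per-day feeding-rate convention
(`1/h`) is the pipeline default because impact comparisons across
experiments with different durations are only meaningful on a common
time base; the per-experiment convention `1/(T h)` is always reported
alongside.

Properties verified by tests: with any positive SEs the ratio mean
exceeds the plug-in ratio (Jensen direction); forward and reverse ratio
means multiply to at least 1; two 10⁵-draw runs with different seeds
agree within 1%.

## Synthetic data

`generate_trials` emulates the laboratory designs: embryo-scale trials
at densities 2–70 (24 h, 5 or more replicates per density) and
larva-scale trials at densities 1–15 (48 h, up to 11 replicates), with
generating parameters at the fitted scales (a ≈ 0.1–0.9 per day,
h ≈ 0.25–6.6 days). Two noise laws:

* `binomial` (default): consumption ~ Binomial(`N_0`, Rogers mean
  proportion). Exactly mean-matched to the deterministic curve and
  exactly matched to the fitting likelihood, so recovery studies are
  well-specified.
* `renewal`: a mechanistic search/handling renewal process —
  exponential search times at rate `a N`, fixed handling `h`, with a
  capture whose handling straddles the horizon credited pro-rata in
  expectation (a Bernoulli draw on the completed fraction). Its mean
  tracks the deterministic curve within ~1–4% at the published-scale
  parameters for `N_0 ≥ 10`; the residual deficit is a genuine
  mean-field effect of stochastic depletion, not a bug, and is why the
  binomial law is the default for estimator studies.

The within-trial variance structure of real trials is unknown; neither
law captures predator individuality (between-individual variance),
satiation dynamics, prey defensive behaviour, or arena geometry.
Passing recovery and calibration tests therefore demonstrates
correctness of the estimator under the model's own assumptions, not
robustness to those biological complications. Background mortality is an
optional independent per-prey Bernoulli applied to survivors, default 0
(observed background mortality in the motivating experiments was
< 1.24%).

`generate_quadrat_survey` draws counts from a negative binomial with
mean density × area and shape `dispersion` (∞ → Poisson), emulating
clumped benthic distributions; it does not model spatial autocorrelation
between neighbouring quadrats.

## Study sizes used in the checks

The shipped test suite sizes its simulation studies as follows: the
recovery study uses 200 replicates per density at the nine-density
embryo design (with a 12-dataset bias comparison at 20 vs 200
replicates); the type-I study uses 500 equal-parameter dataset pairs at
50 replicates per density; the band-coverage study uses 200 datasets at
the laboratory's own 5 replicates per density with 200 bootstrap
resamples each (scaled down from the 2000 used for production bands).

## Known limitations

* Wald inference on (a, h) is asymptotic; at 5 replicates per density
  the tests are conservative (rejection well below nominal α).
* The indicator comparison assumes independent groups; shared predators
  or arenas across groups would violate the block-diagonal information.
* RIP treats the four inputs as independent; correlation between
  feeding rate and abundance (e.g. via body size) is not propagated.
* Abundance pseudo-samples from the literature are treated as
  exchangeable with field quadrats, ignoring between-study variance.
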