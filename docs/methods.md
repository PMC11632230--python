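# Methods

## The frailty index

The frailty index (FI) operationalises the deficit-accumulation model of
frailty: an interview's FI is the mean of its 0–1-coded health-deficit items
(symptoms, diseases, functional limitations, sensory and cognitive problems).
The shipped default catalogue has 40 self-report items; ordinal items are
pre-mapped onto half- or quarter-point grids in `[0, 1]` so that a
deficit-level interquartile range of exactly 0.5 is attainable.  With partial
missingness the denominator is the count of answered items, provided
completeness is at least `min_completeness` (default 0.8, the common FI
guideline); below that the FI is reported missing rather than extrapolated.
Missing answers are empty CSV cells throughout — they are never silently
scored 0.

## Intraindividual variability

Within one measurement burst a person contributes up to 7 biweekly FI values.
Their level is the intraindividual mean (iMean) and their short-term
fluctuation the intraindividual standard deviation (iSD), computed with the
sample (n−1) denominator (`ddof` configurable); a single observation yields a
missing, not zero, iSD.  Deficit-level fluctuation uses the intraindividual
interquartile range (iIQR = Q3 − Q1 of the within-burst item values) with
classes none (iIQR = 0), some (0 < iIQR ≤ 0.5) and high (iIQR > 0.5).
Quantiles use linear interpolation of order statistics (the "type 7" rule,
numpy's default).  The rule matters — the 0.5 class boundary is sensitive to
it — so it is fixed rather than configurable.  The robust/frail cutoff is
0.25: persons are classed by iMean, single assessments by the raw FI, and a
burst series is "threshold inconsistent" when it contains values on both
sides of the cutoff.  Group contrasts in mean iSD (e.g. by chronic disease)
are descriptive, with a seeded person-level bootstrap percentile interval
rather than a parametric test.

## The location-scale model ladder

The core model is a mixed-effects location-scale regression on the long FI
panel.  For person *i*, burst *b*, wave *t*:

    y_ibt ~ Normal(mu_ibt, sigma_ibt^2)
    mu_ibt        = x_ibt' beta + u_i + w_ib + s_ib * wave_c
    log sigma_ibt = z_ibt' gamma + a_i + c_ib

Random effects are jointly Gaussian: person-level `(u_i, a_i)` with SDs
`(tau_u, tau_a)` and correlation `rho_P` (the location–scale correlation:
frailer people fluctuate more), and person×burst-level `(w_ib, s_ib, c_ib)`
with SDs `(tau_w, tau_s, tau_c)`, a location intercept–slope correlation and
a burst-level location–scale correlation; the slope–scale correlation and all
cross-level correlations are fixed at 0.  Scale coefficients are reported
exponentiated, i.e. multiplicative on the residual SD.

The ladder separates the variance sources stepwise:

* **M0** — intercept-only location model with person and person×burst random
  intercepts and a constant residual SD.  Its three variance components give
  the decomposition into stable between-person differences, between-burst
  within-person change, and within-burst short-term fluctuation (always
  normalised to sum to 100%).
* **M1** — adds fixed burst and centred-wave effects plus a random wave slope
  (de-trending the within-burst repeats).
* **M2** — adds the scale submodel with its random effects and the
  location–scale correlations.
* **M3** — adds time-stable covariates (age, sex, education, living
  situation, social support, death between bursts) and interview mode to both
  submodels.
* **M4** — adds the time-varying event indicators (bedrest, fall, hospital
  stay) to both submodels.

Encoding is deterministic: references are men, low education, low social
support, cohabiting, alive, no event, personal interview, burst 1; age is
centred at the person-level sample mean and wave at the within-burst midpoint
(wave 4), so the intercept is the expected FI of the reference person at mean
age mid-burst.

### Observation families

Two observation families are available.  `"normal"` (default) is the model
written above.  `"truncated_normal"` replaces the Gaussian density with a
Normal truncated to `[0, 1]`, the natural law for a bounded proportion such
as the FI — and exactly the law the synthetic generator draws from.  The
distinction is consequential: under the generating parameters roughly 7% of
Gaussian probability mass falls outside `[0, 1]` on average, and refitting a
plain-normal model to truncated data visibly inflates the multiplicative
scale contrasts (the bedrest coefficient by ≈ +0.3).  Parameter-recovery
studies therefore fit with the truncated family; the plain-normal family is
kept as the default because published location-scale analyses of FI panels
use it, and because all closed-form oracles (quadrature equivalence, the
linear-mixed-model limit) are stated for it.

### Estimation

Random effects are integrated out per person: given the parameters, each
person's block `(u_i, a_i, w_i1, s_i1, c_i1, w_i2, s_i2, c_i2)` is
independent, so the marginal likelihood is a sum of per-person integrals.
These are approximated by a block-wise Laplace approximation: a vectorised
per-person Newton ascent finds the conditional modes (saddle-free variant —
the joint density is not concave in the scale coordinates, so per-person
eigenvalue repair plus Levenberg damping for stiff blocks makes the iteration
globally ascending), and the curvature supplies the Gaussian correction.
An adaptive Gauss–Hermite tensor product over the same blocks
(`method="aghq"`, restricted to the data-carrying coordinates) refines the
Laplace value on small problems and is used for oracle tests; Laplace is its
order-1 case and is exact whenever no scale random effects are present.

The default engine maximises the marginal posterior under weakly-informative
priors: Normal(0, 1) on fixed effects (Normal(0, 5) on the two intercepts,
which are far from zero on their natural scales), half-Normal(0, 1) on random
SDs, and LKJ(2) on each correlation block.  The outer optimisation is
L-BFGS-B with the exact analytic gradient of the Laplace objective (envelope
term, the closed-form third-derivative trace of the log-determinant, and the
indirect term through the movement of the modes), diagonally preconditioned
by finite-difference curvature — the raw problem mixes FI-unit fixed effects
and log-SDs whose curvatures differ by ~6 orders of magnitude.  Log-SDs are
box-bounded in `[-8, 2]` so that an effectively-zero variance component
cannot drag the optimiser toward −∞.  For the truncated family the fit is
two-staged: the plain-normal optimum initialises the truncated optimisation,
whose likelihood is violently non-linear where the mean sits far outside the
unit interval.

Uncertainty is summarised from draws of a Gaussian approximation centred at
the posterior mode (numerical Hessian, eigenvalue-clipped to positive
definite); intervals are central 95% ranges of those draws, with scale
coefficients exponentiated and correlations back-transformed from the
Fisher-z scale.  An `emcee` ensemble-sampler engine over the same marginal
posterior provides the MCMC option; split-R̂ ≤ 1.01 and bulk ESS ≥ 400 are
the convergence targets, and fits failing them carry machine-readable
warnings (never silent).

Two behaviours of this estimator are worth knowing.  First, model
comparison: `compare_models` computes PSIS-LOO (or WAIC) on a pointwise
log-likelihood matrix whose unit is by default the *person* — the
exchangeable cluster of a grouped panel — using the per-person marginal
(Laplace) likelihood contributions per posterior draw.  Observation-level
pointwise likelihoods conditional on the random-effect modes are available
too, but conditional leave-one-observation-out is liberal toward richer
random-effect structures and should not be used to compare the ladder.
Second, a subtlety of bounded outcomes: data generated with a floor/ceiling
(FI truncated to `[0, 1]`) are *genuinely* mildly heteroscedastic even when
the generating scale submodel is constant, because truncation compresses
dispersion near the bounds — a scale model fit to such data correctly
reports nonzero scale variance.  Homoscedasticity checks must therefore keep
the mean well inside the interval.  In that regime the scale random SDs
collapse (to ≈ 0.03 at the tested sizes) and the location side matches a
standard linear mixed model (tested against the `statsmodels` `MixedLM`
oracle).

Bayesian R² (fixed effects) is computed per draw as
`var(X beta) / (var(X beta) + random-effect variance + E[sigma^2])`, where the
expected residual variance integrates the log-normal scale random effects,
`E[sigma^2] = exp(2 z'gamma + 2 (tau_a^2 + tau_c^2))`; the posterior mean is
reported.

## The synthetic cohort generator

The generator emulates a two-burst biweekly measurement-burst study of 426
community-dwelling adults aged 70–97: covariate mix (64.6% women, mean age
77.7 (SD 5.4) truncated to [70, 97], education 19.3/54.2/26.5% low/medium/
high, social support 11.6/42.0/46.3% low/medium/high, 66.0% living alone);
wave-1 interviews in person and follow-ups by phone, with a 40-person
all-in-person subsample in burst 1; per-wave retention declining from 98.3%
to 95.3% in burst 1 and from 94.2% to 76.7% (final wave 53.5%) in burst 2;
death between bursts with probability 11/426, then return among survivors
calibrated so the overall between-burst retention is 88.7%.  Health events
(bedrest, fall, hospital stay) are per-interview Bernoulli draws whose
hazards are solved numerically — via the Poisson-binomial distribution of a
person's interview count — so that the person-level prevalence over both
bursts matches 50.9%, 25.4% and 8.9%.

FI values are drawn from the M4 location-scale model above with generating
parameters set to the fitted coefficients of such a study (`DEFAULT_GENERATING_PARAMS`),
and restricted to `[0, 1]` by exact truncated-normal sampling (no point mass
at the bounds).  One reading decision deserves note: the person-level scale
random SD is specified in SD units (0.02 around a reference residual SD of
0.04) in the source table while the burst-level one (0.36) is log-scale; the
generator converts the former by the delta method, sd(log sigma) ≈ 0.02/0.04
= 0.5 — a value consistent with an observed iSD distribution of mean 0.04
and SD 0.03.  Neither cell is asserted as an equality anywhere.

With deficit rendering on, each latent FI is converted to 40 item values
whose mean matches it to within 1/80 (nearest-half-point allocation):
chronic-disease items are switched on once per person and persist across
waves (ratcheting up only if a very high FI requires it), while the remaining
items are re-drawn every wave with selection weights increasing in their
volatility class — mobility/instrumental limitations and cognitive items
switch most, matching where short-term FI fluctuations originate.

What the generator does **not** emulate: seasonal or calendar-time effects,
event clustering beyond what the scale submodel induces, interview-mode
measurement effects beyond a covariate shift, and informative dropout (an
optional switch makes burst-2 dropout depend on the person's frailty level,
off by default).  Event indicators are independent of the random effects, so
event coefficients are identified purely through within-person contrasts.
Passing recovery tests therefore demonstrates internal consistency of
generator + estimator at the study's design size — not that the model is
correct for any particular real cohort.

## Problem sizes and test design

The parameter-recovery harness uses 10 simulated replicates at the full
design size (426 persons, ~5 100 interviews) fitted with M4 under the
truncated family; recovered quantities are averaged across replicates.
Generator calibration checks use 200 simulation replicates (no fitting).
Model-comparison direction checks (heteroscedastic data prefer M2 over M1 by
|Δelpd| > 2·SE; homoscedastic data do not) run at 150 persons.  Oracle
equivalences run on 2-person toys where brute-force quadrature is exact.
These sizes are the package's own choices balancing Monte-Carlo error
against quick iteration.

## Known limitations

* The Laplace approximation slightly biases scale-variance components with
  very short within-burst series; the adaptive quadrature path quantifies
  this on small examples but is not feasible at design scale.
* The burst-level wave-slope SD is generated near zero (0.002), so the
  location intercept–slope correlation is only weakly identified; its
  estimate should not be over-read.
* Credible intervals from the map engine are Gaussian approximations at the
  mode; for strongly skewed posteriors (small variance components) prefer
  the mcmc engine.
* Person-level LOO treats the whole person as the held-out unit; a
  marginal leave-one-observation-out (integrating random effects per left-out
  row) is not implemented.
* The truncated family's posterior is strongly non-Gaussian when many
  observations sit exactly on a bound (e.g. FI computed from rendered items,
  where robust persons score exactly 0 at every wave): point estimates are
  fine, but the mode-centred Gaussian draws — hence credible intervals, LOO
  and R² — are unreliable and the fit flags its curvature warning.  Use the
  plain-normal family for interval summaries on such data, or fit the
  truncated family with `compute_uncertainty=False`.
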