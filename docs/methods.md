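# Methods

## Survival model

Counts of live nematodes at scoring times `t_1 < … < t_m` are modelled as

    y_i ~ Binomial(n_i, p_i),    logit(p_i) = η(t_i) = Σ_{k=0..d} β_k t_i^k

with polynomial degree `d = 1` (linear) or `d = 3` (cubic); other degrees
are rejected rather than silently accepted, because with a handful of
timepoints higher degrees invite oscillating fits whose 50% crossings are
not meaningful. The model assumes every animal is available for scoring
at every timepoint (sampling is treated as with-replacement draws from
one pooled arm) and that the survival curve is smooth on the logit scale.

**Fitting.** Maximum likelihood by iteratively reweighted least squares.
The time covariate is centred and scaled internally (`z = (t − t̄)/sd(t)`)
— powers of raw days up to `t³` are badly conditioned — and coefficients
are mapped back to the raw day scale through the exact binomial-expansion
linear map, so the reported `β_k` multiply plain powers of days.
Initialization is the least-squares fit to Haldane-corrected empirical
logits, `log((y+½)/(n−y+½))`, which is finite even when end timepoints
have 0 or n alive. Convergence is declared when the largest absolute
coefficient change falls below 1e−8 (default; at most 100 iterations); a
non-converged fit is returned flagged, with a warning logged. If the
linear predictor exceeds |η| = 30 at any data timepoint the likelihood is
effectively unbounded (separation) and the fit aborts with an explicit
error instead of returning garbage coefficients.

**Overdispersion.** Scored counts are often noisier than binomial
(clumping, flask effects). The quasi-likelihood moment estimator
`φ = Pearson χ² / df_residual` scales the coefficient covariance
(information inverse × φ). φ is floored at 1.0 by default: extra-binomial
noise may widen intervals, but apparent *under*dispersion — usually a
small-sample artifact — is not allowed to shrink them. Pearson rather
than deviance χ² is the default estimator; it is the standard
quasi-binomial moment choice and the two differ negligibly for these
sample sizes. For a saturated fit (as many parameters as timepoints) the
dispersion is undefined; the `pearson_dispersion` operation raises, while
`fit_logistic_survival` still returns the (interpolating) model with φ
set to the floor so that closed-form two-point fits remain usable.

## Median lifespan and its interval

The median is the root of `η(t) = 0` where survival falls through 50%.
Fitted cubics can cross 50% more than once, so the root is selected by
rule: scan a dense grid (4001 points) over the data window extended by
25% on each side, keep the crossings where η goes positive→negative, and
refine by bisection to 1e−9 days. No descending crossing is an error
("median not reached"); several are an ambiguity error listing all
candidates, leaving the choice to the caller rather than guessing. The
25% extension lets a median slightly beyond the last scoring day be
found while keeping the search local to the data.

**Bootstrap.** For each of B resamples (default B = 1000; 300 in the
heavier simulation loops), alive counts are drawn independently per
timepoint from `Binomial(n_i, p̂_i)` with `p̂_i` the **observed**
proportion alive — not the fitted one; resampling the raw proportions is
the more model-agnostic choice, and fitted-proportion resampling is
available as an option. The model is refitted to each resample and its
median recorded; resamples whose fit fails or whose median is undefined
are excluded and counted, and the estimate is refused if 5% or more
fail. The 95% limits are the 2.5th and 97.5th percentiles of the
retained bootstrap medians, computed with the linear-interpolation
order-statistic convention (`numpy.percentile` default). The percentile
interval does not guarantee `ci_low ≤ point ≤ ci_high`, though in
practice it holds; `ci_low ≤ ci_high` always does.

Resamples are plain binomial even when the generating process is
overdispersed; with intra-class correlation ρ > 0 the interval will
undercover. Beta-binomial resampling (`resample_rho`) is provided for
sensitivity analysis but is deliberately not the default.

**Coverage validation.** `coverage_experiment` simulates independent
assays from a known curve, bootstraps each, and reports the fraction of
intervals containing the true median. At the reference design — cubic
curve with true median 18.17 days, 100 worms per timepoint, days 2–34
every 2 days, ρ = 0, 200 replicates, B = 300 — coverage lands within
Monte-Carlo bounds of the nominal 95% (the acceptance script recomputes
this; a typical run gives ~93–96%). These problem sizes were chosen so a
full coverage run completes in about a minute on one CPU while keeping
the binomial Monte-Carlo error on the coverage estimate near 1.5
percentage points.

## Synthetic data

**Lifespan generator.** Inverts the estimation model: given a true
logit-polynomial curve and a design (timepoints, n per timepoint, seed),
draws alive counts binomially, or beta-binomially with intra-class
correlation ρ for mean-preserving variance inflation `1 + (n−1)ρ` — a
single-parameter mechanism standing in for whatever produced the excess
variability in real assays. Defaults: 100 worms per timepoint, scoring
every 2 days from day 2 to day 34, a span that brackets typical medians
(10–25 days) under both control and exposed conditions. The reference
cubic curve `η(t) = 4 − 0.05t − 0.013t² + 0.0002t³` starts near 98%
survival at day 2, falls through 50% at 18.17 days and below 1% by day
34.

**Plate generator.** Worm counts per well are rounded
`Normal(30, 5.1)` truncated (by rejection) to [17, 45], matching
observed per-column means/SEMs and the recorded extremes of wells seeded
from shaken liquid culture. Luminescence is
`count × per-worm yield × treatment multiplier × LogNormal` with the
log-normal scaled to unit mean and a configurable coefficient of
variation (default 0.1) — a multiplicative model because the signal is
positive with replicate CVs roughly independent of level. Fluorescence
is `count × per-worm fluorescence + background`. Treatment effects are
phenomenological multipliers; no growth, egg-laying or ATP kinetics are
simulated, so passing tests demonstrate that the *pipeline* recovers
programmed effects under realistic count and measurement noise, not that
any biological mechanism is captured. Real plates also carry edge
effects, pipetting drift and plate-to-plate batch structure that the
generator does not emulate.

A note on what the generator's variability implies downstream: with 24
wells per arm (3 technical replicates of 8) the per-well luminescence CV
is ≈ √(0.163² + 0.1²) ≈ 0.19 (count spread dominating measurement
noise), so a percent-of-control readout of a 0.55× effect carries a
standard deviation of about 3 percentage points. A ±5-point window
around 55% is therefore a ~1.65σ band and captures roughly 90% of
simulated plates — averaging over more wells or replicates is what
tightens it.

## Plate reduction

Background is subtracted per channel with a floor at zero (clamped wells
are counted and logged). Wells are grouped into technical replicates of
`group_size ≥ 5` (default 8, one plate column) per (treatment,
timepoint), in column order; leftover wells are an error rather than a
silently dropped remainder. Each replicate carries the mean and SEM
(sample SD/√n) of member luminescence. Percent of control is
`100 × mean(treatment replicate means) / mean(control replicate means)`
per timepoint, with the control pooled across its replicates at that
timepoint; the SEM of the normalized value is propagated from the
treatment replicate spread only, the control mean being treated as a
fixed scale. For balanced designs normalizing per-replicate means and
normalizing the grand well mean coincide exactly.

## Numerical and design choices

* Percentile definition, root-selection rule, IRLS initialization and
  the η-limit for declaring separation are all stated above and covered
  by tests; they are conventions, and alternatives (e.g. nearest-rank
  percentiles, Newton root polishing) would change results only at the
  margins.
* All randomness flows through `numpy.random.default_rng` seeded
  explicitly; identical configuration and seed give byte-identical
  outputs. Replicate-level seeds in simulation studies are drawn from a
  single parent generator so the whole study is reproducible from one
  integer.
* CSV dialects are fixed-header, UTF-8, dot-decimal; floats round-trip
  exactly (`%.17g` on write, round-trip parsing on read).

## Limitations

* The bootstrap ignores overdispersion by default (see above) and
  resamples timepoints independently, so serial correlation across
  scoring times is not propagated into the intervals.
* Scoring is modelled as sampling with replacement from one pooled arm;
  assays where sampled animals are removed, or where flask-level
  structure matters, violate this.
* No between-treatment significance testing is provided; the package
  estimates arm-wise medians and intervals only.
* The plate pipeline takes reader values as given: integration time,
  luciferin chemistry and any nonlinearity of the luminometer are
  upstream of this package.
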