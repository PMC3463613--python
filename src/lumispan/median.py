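"""Median lifespan estimation and percentile-bootstrap confidence intervals.

The median lifespan is the time at which the fitted survival curve
crosses 50%.  Confidence limits come from a parametric bootstrap:
alive counts are resampled from binomial distributions at the observed
per-timepoint proportions, the model is refitted to each resample, and
the 2.5th/97.5th percentiles of the bootstrap medians form the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._roots import (
    AmbiguousMedianError,
    MedianNotReachedError,
    find_descending_root,
)
from .simulate import LifespanDesign, TrueSurvivalCurve, simulate_lifespan_series
from .survival import (
    FittedSurvivalModel,
    ModelConfig,
    SeparationError,
    SurvivalSeries,
    fit_logistic_survival,
)

__all__ = [
    "MedianEstimate",
    "CoverageResult",
    "estimate_median",
    "bootstrap_median_ci",
    "coverage_experiment",
    "MedianNotReachedError",
    "AmbiguousMedianError",
]

#: fraction of the data window added on each side when hunting the median
_WINDOW_EXTENSION = 0.25

#: a reported interval requires fewer than this fraction of failed resamples
_MAX_FAILED_FRACTION = 0.05


@dataclass(frozen=True)
class MedianEstimate:
    """Median lifespan with its 95% percentile-bootstrap interval (days)."""

    point: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    n_failed_resamples: int
    seed: int
    bootstrap_medians: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class CoverageResult:
    """Outcome of a coverage simulation for the bootstrap interval."""

    coverage: float
    n_success: int
    n_requested: int
    true_median: float
    records: list[dict] = field(repr=False)


def estimate_median(model: FittedSurvivalModel) -> float:
    """Time at which the fitted survival curve falls through 50%.

    The search window is the data window widened by 25% on each side.
    Among sign changes of the linear predictor on a dense grid, the
    positive-to-negative crossing is selected and refined by bisection to
    1e-9 days.  Errors if no descending crossing exists or several do.
    """
    lo, hi = model.data_window
    pad = _WINDOW_EXTENSION * (hi - lo)
    try:
        return find_descending_root(model.coefficients, (lo - pad, hi + pad))
    except MedianNotReachedError:
        raise MedianNotReachedError(
            f"median not reached within window ({lo - pad:g}, {hi + pad:g})"
        ) from None


def bootstrap_median_ci(
    series: SurvivalSeries,
    config: ModelConfig,
    B: int = 1000,
    seed: int = 0,
    resample_from: str = "observed",
    resample_rho: float = 0.0,
) -> MedianEstimate:
    """Percentile-bootstrap 95% interval for the median lifespan.

    For each of ``B`` resamples, alive counts are drawn independently per
    timepoint from Binomial(n_scored_i, p_i) with p_i the OBSERVED
    survival proportion (``resample_from="fitted"`` substitutes the
    model-fitted proportions; ``resample_rho > 0`` switches to
    beta-binomial resampling with that intra-class correlation).  Each
    resample is refitted with the same model and its median recorded;
    resamples whose fit or median fails are excluded and counted.  The
    interval is the 2.5th and 97.5th percentiles (linear interpolation)
    of the retained bootstrap medians.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if resample_from not in ("observed", "fitted"):
        raise ValueError("resample_from must be 'observed' or 'fitted'")

    model = fit_logistic_survival(series, config)
    point = estimate_median(model)

    if resample_from == "observed":
        p = series.proportions
    else:
        p = model.fitted_proportions
    n = series.n_scored
    t = series.timepoints

    rng = np.random.default_rng(seed)
    medians = np.empty(B)
    n_failed = 0
    n_ok = 0
    for _ in range(B):
        if resample_rho > 0.0:
            s = (1.0 - resample_rho) / resample_rho
            with np.errstate(invalid="ignore"):
                probs = rng.beta(p * s, (1.0 - p) * s)
            probs = np.where(p <= 0.0, 0.0, np.where(p >= 1.0, 1.0, probs))
        else:
            probs = p
        alive = rng.binomial(n, probs)
        try:
            boot = SurvivalSeries(t, n, alive, series.treatment)
            medians[n_ok] = estimate_median(fit_logistic_survival(boot, config))
            n_ok += 1
        except (
            ValueError,
            SeparationError,
            MedianNotReachedError,
            AmbiguousMedianError,
            np.linalg.LinAlgError,
        ):
            n_failed += 1

    if n_failed >= _MAX_FAILED_FRACTION * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap resamples failed; widen the time "
            "window or lower the polynomial degree"
        )
    kept = medians[:n_ok]
    ci_low, ci_high = np.percentile(kept, [2.5, 97.5])
    return MedianEstimate(
        point=point,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_bootstrap=B,
        n_failed_resamples=n_failed,
        seed=seed,
        bootstrap_medians=kept,
    )


def coverage_experiment(
    curve: TrueSurvivalCurve,
    design: LifespanDesign,
    reps: int,
    B: int,
    config: ModelConfig,
    seed: int = 0,
) -> CoverageResult:
    """Fraction of bootstrap intervals that contain the true median.

    Simulates ``reps`` independent series from ``curve`` under ``design``
    (per-rep seeds derived from ``seed``), computes the bootstrap interval
    for each, and returns the empirical coverage with a per-rep log.
    Aborts if more than 10% of replicates fail outright.
    """
    if curve.true_median is None:
        raise ValueError("curve.true_median must be set for a coverage run")
    truth = curve.true_median
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=(reps, 2))

    records: list[dict] = []
    n_hit = 0
    n_success = 0
    for r in range(reps):
        rep_design = LifespanDesign(
            timepoints=design.timepoints,
            n_per_timepoint=design.n_per_timepoint,
            overdispersion_rho=design.overdispersion_rho,
            seed=int(rep_seeds[r, 0]),
        )
        try:
            series = simulate_lifespan_series(curve, rep_design)
            est = bootstrap_median_ci(
                series, config, B=B, seed=int(rep_seeds[r, 1])
            )
        except Exception as exc:  # logged per rep, not fatal below 10%
            records.append({"rep": r, "error": str(exc)})
            continue
        hit = bool(est.ci_low <= truth <= est.ci_high)
        n_success += 1
        n_hit += hit
        records.append(
            {
                "rep": r,
                "point": est.point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "covers": hit,
            }
        )

    if n_success < 0.9 * reps:
        raise RuntimeError(
            f"only {n_success}/{reps} coverage replicates succeeded"
        )
    return CoverageResult(
        coverage=n_hit / n_success,
        n_success=n_success,
        n_requested=reps,
        true_median=truth,
        records=records,
    )
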