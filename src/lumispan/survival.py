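"""Quasi-binomial logit-polynomial survival models.

Proportions of nematodes alive at each scoring time are modelled as
inverse-logit of a polynomial in time (degree 1 or 3), fitted by
iteratively reweighted least squares on the binomial log-likelihood.
Extra-binomial variability of the counts is absorbed by a Pearson
overdispersion parameter that scales the coefficient covariance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalSeries",
    "ModelConfig",
    "FittedSurvivalModel",
    "SeparationError",
    "SaturatedModelError",
    "fit_logistic_survival",
    "predict_survival",
    "pearson_dispersion",
]

#: linear-predictor magnitude beyond which the fit is treated as separated
_ETA_LIMIT = 30.0


class SeparationError(RuntimeError):
    """The likelihood is unbounded: fitted logits diverge (complete separation)."""


class SaturatedModelError(ValueError):
    """Raised where a quantity is undefined for a saturated fit."""


@dataclass(frozen=True)
class SurvivalSeries:
    """Per-timepoint counts of scored and alive nematodes for one arm.

    ``timepoints`` are in days and must be strictly increasing;
    ``n_alive[i] <= n_scored[i]`` everywhere.
    """

    timepoints: np.ndarray
    n_scored: np.ndarray
    n_alive: np.ndarray
    treatment: str = ""

    def __post_init__(self):
        t = np.asarray(self.timepoints, dtype=float)
        n = np.asarray(self.n_scored, dtype=int)
        y = np.asarray(self.n_alive, dtype=int)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("a survival series needs at least 2 timepoints")
        if not (np.diff(t) > 0).all():
            raise ValueError("timepoints must be strictly increasing")
        if t.size != n.size or t.size != y.size:
            raise ValueError("timepoints, n_scored and n_alive must align")
        if (n < 1).any():
            raise ValueError("n_scored must be positive at every timepoint")
        if (y < 0).any() or (y > n).any():
            raise ValueError("need 0 <= n_alive <= n_scored at every timepoint")
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "n_scored", n)
        object.__setattr__(self, "n_alive", y)

    @property
    def proportions(self) -> np.ndarray:
        """Observed survival proportions p_hat_i."""
        return self.n_alive / self.n_scored

    def __len__(self) -> int:
        return self.timepoints.size


@dataclass(frozen=True)
class ModelConfig:
    """Fitting options; only linear and cubic time polynomials are allowed."""

    degree: int = 1
    max_iterations: int = 100
    tolerance: float = 1e-8
    dispersion_floor: float = 1.0

    def __post_init__(self):
        if self.degree not in (1, 3):
            raise ValueError(
                f"degree must be 1 (linear) or 3 (cubic), got {self.degree}"
            )
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class FittedSurvivalModel:
    """Logit-polynomial fit: coefficients on the raw day scale.

    ``covariance`` is the IRLS information inverse scaled by the floored
    dispersion; ``fitted_proportions`` are the model survival probabilities
    at the data timepoints.
    """

    coefficients: np.ndarray
    dispersion: float
    covariance: np.ndarray
    pearson_chi2: float
    deviance: float
    df_residual: int
    converged: bool
    data_window: tuple[float, float]
    fitted_proportions: np.ndarray = field(repr=False)

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def linear_predictor(self, t):
        """eta(t) = sum_k beta_k t^k on the day scale."""
        return np.polynomial.polynomial.polyval(t, self.coefficients)

    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


def _scaled_design(t: np.ndarray, degree: int):
    """Centred/scaled time powers; returns (X, centre, scale)."""
    centre = t.mean()
    scale = t.std()
    z = (t - centre) / scale
    return np.vander(z, degree + 1, increasing=True), centre, scale


def _raw_scale_transform(degree: int, centre: float, scale: float) -> np.ndarray:
    """Matrix M with beta_raw = M @ gamma_scaled for z = (t - centre)/scale."""
    M = np.zeros((degree + 1, degree + 1))
    for k in range(degree + 1):
        for j in range(k + 1):
            M[j, k] = math.comb(k, j) * (-centre) ** (k - j) / scale**k
    return M


def _irls(X, n, y, max_iterations, tolerance):
    """IRLS for binomial counts with logit link on design X.

    Returns (gamma, information matrix, converged flag).  Starts from the
    least-squares fit to Haldane-corrected empirical logits so that 0 and n
    counts at the end timepoints pose no problem.
    """
    eta0 = np.log((y + 0.5) / (n - y + 0.5))
    gamma, *_ = np.linalg.lstsq(X, eta0, rcond=None)
    converged = False
    info = None
    for _ in range(max_iterations):
        eta = X @ gamma
        if np.max(np.abs(eta)) > _ETA_LIMIT:
            raise SeparationError(
                "fit diverging: |eta| exceeds "
                f"{_ETA_LIMIT:g} at a data timepoint (separation)"
            )
        p = expit(eta)
        w = n * p * (1.0 - p)
        z = eta + (y - n * p) / w
        Xw = X.T * w
        info = Xw @ X
        new_gamma = np.linalg.solve(info, Xw @ z)
        step = np.max(np.abs(new_gamma - gamma))
        gamma = new_gamma
        if step < tolerance:
            converged = True
            break
    return gamma, info, converged


def _binomial_deviance(n, y, p) -> float:
    mu = n * p
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        term2 = np.where(y < n, (n - y) * np.log((n - y) / (n - mu)), 0.0)
    return float(2.0 * np.sum(term1 + term2))


def fit_logistic_survival(
    series: SurvivalSeries, config: ModelConfig = ModelConfig()
) -> FittedSurvivalModel:
    """Fit the binomial-logit polynomial survival model.

    The time covariate is centred and scaled internally for numerical
    stability; reported coefficients are on the raw day scale.  The
    coefficient covariance is the information inverse multiplied by the
    Pearson dispersion floored at ``config.dispersion_floor``, so
    overdispersion can widen intervals but never shrink them.
    """
    t = series.timepoints
    n = series.n_scored.astype(float)
    y = series.n_alive.astype(float)
    n_params = config.degree + 1
    if len(series) < n_params:
        raise ValueError(
            f"need at least {n_params} timepoints for degree {config.degree}"
        )
    if (y == 0).all() or (y == n).all():
        raise ValueError(
            "cannot fit: all proportions are 0 or all are 1 (no information)"
        )

    X, centre, scale = _scaled_design(t, config.degree)
    gamma, info, converged = _irls(
        X, n, y, config.max_iterations, config.tolerance
    )
    if not converged:
        logger.warning(
            "IRLS did not converge within %d iterations (treatment=%r)",
            config.max_iterations,
            series.treatment,
        )

    p = expit(X @ gamma)
    chi2 = float(np.sum((y - n * p) ** 2 / (n * p * (1.0 - p))))
    deviance = _binomial_deviance(n, y, p)
    df = len(series) - n_params
    if df >= 1:
        phi = max(chi2 / df, config.dispersion_floor)
    else:
        # saturated fit: dispersion not estimable; floor keeps the
        # covariance defined
        phi = config.dispersion_floor

    M = _raw_scale_transform(config.degree, centre, scale)
    beta = M @ gamma
    cov_gamma = np.linalg.inv(info)
    covariance = phi * (M @ cov_gamma @ M.T)

    return FittedSurvivalModel(
        coefficients=beta,
        dispersion=phi,
        covariance=covariance,
        pearson_chi2=chi2,
        deviance=deviance,
        df_residual=df,
        converged=converged,
        data_window=(float(t[0]), float(t[-1])),
        fitted_proportions=p,
    )


def predict_survival(model: FittedSurvivalModel, t):
    """Model survival proportion at time ``t`` (days): inverse-logit(eta(t)).

    Extrapolation outside the fitted data window is permitted but logged.
    """
    t_arr = np.asarray(t, dtype=float)
    lo, hi = model.data_window
    if np.any(t_arr < lo) or np.any(t_arr > hi):
        logger.info(
            "predicting outside the fitted data window (%g, %g)", lo, hi
        )
    out = expit(model.linear_predictor(t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def pearson_dispersion(
    model: FittedSurvivalModel,
    series: SurvivalSeries,
    dispersion_floor: float = 1.0,
) -> float:
    """Pearson chi-square / df dispersion, floored at ``dispersion_floor``.

    phi = sum_i (y_i - n_i p_i)^2 / (n_i p_i (1 - p_i)) / df_residual,
    with p_i the fitted proportions.
    """
    if model.df_residual < 1:
        raise SaturatedModelError("dispersion undefined for saturated fit")
    n = series.n_scored.astype(float)
    y = series.n_alive.astype(float)
    p = expit(model.linear_predictor(series.timepoints))
    chi2 = float(np.sum((y - n * p) ** 2 / (n * p * (1.0 - p))))
    return max(chi2 / model.df_residual, dispersion_floor)
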