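"""Synthetic lifespan-count series and 96-well plate assays.

The lifespan generator inverts the estimation model of the analysis: a
true survival curve S(t) = inverse-logit of a polynomial in time, with
~100 worms scored alive/dead at each timepoint, drawn binomially (or
beta-binomially when extra-binomial variability is wanted).  The plate
generator emulates wells seeded with ~30 worms (observed range 17-45)
whose bioluminescence is proportional to worm number, with multiplicative
log-normal measurement noise, grouped into technical replicates of >= 5
wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._roots import find_descending_root
from .survival import SurvivalSeries

__all__ = [
    "TrueSurvivalCurve",
    "LifespanDesign",
    "PlateSimConfig",
    "WellRecord",
    "simulate_lifespan_series",
    "true_median",
    "simulate_plate",
    "default_cubic_curve",
    "default_lifespan_timepoints",
]

PLATE_ROWS = "ABCDEFGH"
PLATE_COLS = 12


@dataclass(frozen=True)
class TrueSurvivalCurve:
    """Ground-truth survival curve: logit of survival is polynomial in time.

    ``coefficients`` are beta_0..beta_d on the logit/day scale;
    ``time_window`` (days) bounds where the curve is meant to be used.
    ``true_median`` may record the known 50% crossing for validation.
    """

    coefficients: tuple[float, ...]
    time_window: tuple[float, float]
    true_median: float | None = None

    def __post_init__(self):
        coeffs = tuple(float(c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coeffs)
        lo, hi = self.time_window
        if not (0 <= lo < hi):
            raise ValueError("time_window must satisfy 0 <= start < end")
        if self.true_median is not None:
            m = float(self.true_median)
            if not (lo <= m <= hi):
                raise ValueError("true_median must lie in time_window")
            if abs(self.survival(m) - 0.5) > 1e-9:
                raise ValueError("S(true_median) must equal 0.5 within 1e-9")

    def linear_predictor(self, t):
        return np.polynomial.polynomial.polyval(t, self.coefficients)

    def survival(self, t):
        """S(t), always strictly inside (0, 1)."""
        return expit(self.linear_predictor(t))


@dataclass(frozen=True)
class LifespanDesign:
    """Sampling design of a lifespan assay: when and how many worms scored.

    Defaults mirror the assay: ~100 worms scored per timepoint at regular
    timepoints spanning the lifespan.  ``overdispersion_rho`` is the
    beta-binomial intra-class correlation (0 = pure binomial counts).
    """

    timepoints: tuple[float, ...] = field(
        default_factory=lambda: default_lifespan_timepoints()
    )
    n_per_timepoint: int = 100
    overdispersion_rho: float = 0.0
    seed: int = 0

    def __post_init__(self):
        t = tuple(float(x) for x in self.timepoints)
        object.__setattr__(self, "timepoints", t)
        if len(t) < 1 or not all(b > a for a, b in zip(t, t[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.n_per_timepoint < 1:
            raise ValueError("n_per_timepoint must be >= 1")
        if not 0.0 <= self.overdispersion_rho < 1.0:
            raise ValueError("overdispersion_rho must be in [0, 1)")


def default_lifespan_timepoints() -> tuple[float, ...]:
    """Scoring every 2 days from day 2 to day 34 (spans typical medians)."""
    return tuple(float(t) for t in range(2, 36, 2))


def default_cubic_curve() -> TrueSurvivalCurve:
    """Reference cubic-logit curve with its 50% crossing near day 18.

    Survival starts near 98% at day 2 and falls below 1% by day 34,
    the shape of an FUdR-arm lifespan assay.
    """
    coefficients = (4.0, -0.05, -0.013, 0.0002)
    window = (0.0, 40.0)
    median = find_descending_root(coefficients, window)
    return TrueSurvivalCurve(coefficients, window, true_median=median)


def simulate_lifespan_series(
    curve: TrueSurvivalCurve, design: LifespanDesign
) -> SurvivalSeries:
    """Draw alive counts at each design timepoint from the true curve.

    Counts are Binomial(n, S(t)) when ``overdispersion_rho`` is 0, and
    beta-binomial with the same mean and intra-class correlation rho
    otherwise (variance inflated by 1 + (n-1) rho).  Identical design seed
    gives identical output.
    """
    lo, hi = curve.time_window
    for t in design.timepoints:
        if not (lo <= t <= hi):
            raise ValueError(
                f"timepoint {t:g} outside curve time_window ({lo:g}, {hi:g})"
            )
    rng = np.random.default_rng(design.seed)
    t = np.asarray(design.timepoints)
    p = curve.survival(t)
    n = design.n_per_timepoint
    rho = design.overdispersion_rho
    if rho == 0.0:
        alive = rng.binomial(n, p)
    else:
        # beta-binomial via beta-distributed per-timepoint probabilities;
        # shape a + b = (1 - rho)/rho keeps the mean at S(t)
        s = (1.0 - rho) / rho
        alive = rng.binomial(n, rng.beta(p * s, (1.0 - p) * s))
    return SurvivalSeries(
        timepoints=t,
        n_scored=np.full(t.size, n, dtype=int),
        n_alive=alive,
        treatment="simulated",
    )


def true_median(curve: TrueSurvivalCurve) -> float:
    """Time at which the true curve falls through 50% survival.

    Located by a dense grid scan over the curve's time window followed by
    bisection; errors if the curve never reaches 50% or crosses more than
    once going down.
    """
    return find_descending_root(curve.coefficients, curve.time_window)


@dataclass(frozen=True)
class WellRecord:
    """One 96-well plate well: position, treatment and both reader channels."""

    plate_id: str
    row: str
    col: int
    treatment: str
    timepoint_h: float
    luminescence: float
    fluorescence: float
    worm_count: int | None = None

    def __post_init__(self):
        if self.row not in PLATE_ROWS:
            raise ValueError(f"row must be one of {PLATE_ROWS!r}, got {self.row!r}")
        if not 1 <= self.col <= PLATE_COLS:
            raise ValueError(f"col must be in 1..{PLATE_COLS}, got {self.col}")
        if self.luminescence < 0 or self.fluorescence < 0:
            raise ValueError("readings must be non-negative")
        if self.timepoint_h < 0:
            raise ValueError("timepoint_h must be non-negative")

    @property
    def well(self) -> str:
        """Letter-number well label, e.g. ``A1``."""
        return f"{self.row}{self.col}"


@dataclass(frozen=True)
class PlateSimConfig:
    """Plate-assay generator settings.

    Worm counts per well follow a rounded normal truncated to
    [min_worms, max_worms]; defaults match the observed well statistics
    (mean ~30, column SEM ~1.8 over 8 wells, extremes 17-45).
    Luminescence is worm count x per-worm yield x treatment multiplier,
    with multiplicative log-normal noise of coefficient of variation
    ``noise_cv``.  Fluorescence is worm count x per-worm fluorescence plus
    a constant background.
    """

    treatment_effects: dict[str, float]
    seed: int
    mean_worms_per_well: float = 30.0
    sd_worms_per_well: float = 5.1
    min_worms: int = 17
    max_worms: int = 45
    per_worm_yield: float = 100.0
    per_worm_fluorescence: float = 10.0
    noise_cv: float = 0.1
    background_fluorescence: float = 0.0
    wells_per_replicate: int = 8

    def __post_init__(self):
        if self.min_worms > self.max_worms:
            raise ValueError("min_worms must be <= max_worms")
        if self.wells_per_replicate < 5:
            raise ValueError(
                "wells_per_replicate must be >= 5 (minimum of 5 wells "
                "per technical replicate)"
            )
        if self.noise_cv < 0 or self.background_fluorescence < 0:
            raise ValueError("noise_cv and background_fluorescence must be >= 0")
        for label, effect in self.treatment_effects.items():
            if effect <= 0:
                raise ValueError(f"treatment effect for {label!r} must be > 0")


def _truncated_worm_counts(config: PlateSimConfig, size: int, rng) -> np.ndarray:
    counts = np.empty(size, dtype=int)
    filled = 0
    while filled < size:
        draw = np.rint(
            rng.normal(config.mean_worms_per_well, config.sd_worms_per_well, size)
        ).astype(int)
        ok = draw[(draw >= config.min_worms) & (draw <= config.max_worms)]
        take = min(ok.size, size - filled)
        counts[filled : filled + take] = ok[:take]
        filled += take
    return counts


def simulate_plate(
    config: PlateSimConfig,
    n_wells_per_treatment: int,
    timepoint_h: float,
    treatments: list[str] | None = None,
) -> list[WellRecord]:
    """Simulate plate wells for each treatment, filled in column order.

    Treatments occupy consecutive wells down the columns (8 rows per
    column), spilling onto further plates as needed.  Identical config
    seed gives an identical plate.
    """
    if treatments is None:
        treatments = list(config.treatment_effects)
    for label in treatments:
        if label not in config.treatment_effects:
            raise KeyError(
                f"treatment {label!r} missing from treatment_effects"
            )
    if n_wells_per_treatment < config.wells_per_replicate:
        raise ValueError(
            "n_wells_per_treatment must be >= wells_per_replicate "
            f"({config.wells_per_replicate})"
        )
    rng = np.random.default_rng(config.seed)
    sigma = float(np.sqrt(np.log1p(config.noise_cv**2)))

    records: list[WellRecord] = []
    position = 0  # running well index, column-major across plates
    for label in treatments:
        effect = config.treatment_effects[label]
        counts = _truncated_worm_counts(config, n_wells_per_treatment, rng)
        if sigma > 0.0:
            noise = rng.lognormal(-0.5 * sigma**2, sigma, n_wells_per_treatment)
        else:
            noise = np.ones(n_wells_per_treatment)
        lum = counts * config.per_worm_yield * effect * noise
        fluo = counts * config.per_worm_fluorescence + config.background_fluorescence
        for i in range(n_wells_per_treatment):
            plate, rem = divmod(position, len(PLATE_ROWS) * PLATE_COLS)
            col, row = divmod(rem, len(PLATE_ROWS))
            records.append(
                WellRecord(
                    plate_id=f"P{plate + 1}",
                    row=PLATE_ROWS[row],
                    col=col + 1,
                    treatment=label,
                    timepoint_h=float(timepoint_h),
                    luminescence=float(lum[i]),
                    fluorescence=float(fluo[i]),
                    worm_count=int(counts[i]),
                )
            )
            position += 1
    return records
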