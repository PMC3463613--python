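"""Descending-root location for logit-scale survival polynomials.

The median lifespan is the time at which the linear predictor
eta(t) = sum_k beta_k t^k crosses zero from above (survival falling
through 50%).  A dense grid scan locates sign changes; each candidate
bracket is refined by bisection.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "MedianNotReachedError",
    "AmbiguousMedianError",
    "find_descending_root",
]


class MedianNotReachedError(ValueError):
    """The survival polynomial never falls through 50% in the window."""


class AmbiguousMedianError(ValueError):
    """More than one descending 50% crossing in the window."""

    def __init__(self, candidates):
        self.candidates = list(candidates)
        super().__init__(
            "multiple descending 50% crossings in window: "
            + ", ".join(f"{c:.6g}" for c in self.candidates)
            + "; narrow the window"
        )


def _horner(coefficients, t: float) -> float:
    acc = 0.0
    for c in reversed(coefficients):
        acc = acc * t + c
    return acc


def _bisect(coefficients, lo: float, hi: float, xtol: float) -> float:
    # invariant: eta(lo) > 0 >= eta(hi)
    while hi - lo > xtol:
        mid = 0.5 * (lo + hi)
        if _horner(coefficients, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def find_descending_root(
    coefficients,
    window: tuple[float, float],
    n_grid: int = 4001,
    xtol: float = 1e-9,
) -> float:
    """Unique time in ``window`` where the polynomial crosses zero going down.

    Raises
    ------
    MedianNotReachedError
        if no positive-to-negative crossing exists in the window.
    AmbiguousMedianError
        if more than one descending crossing is found.
    """
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise ValueError(f"window must satisfy start < end, got {window}")
    coefficients = [float(c) for c in coefficients]
    grid = np.linspace(lo, hi, n_grid)
    eta = np.polynomial.polynomial.polyval(grid, coefficients)

    roots: list[float] = []
    for i in range(n_grid - 1):
        if eta[i] > 0.0 and eta[i + 1] <= 0.0:
            if eta[i + 1] == 0.0:
                # grid point is the root only if the curve keeps falling
                if i + 2 < n_grid and eta[i + 2] >= 0.0:
                    continue
                roots.append(float(grid[i + 1]))
            else:
                roots.append(_bisect(coefficients, grid[i], grid[i + 1], xtol))

    if not roots:
        raise MedianNotReachedError(
            f"curve never reaches 50% in window ({lo:g}, {hi:g})"
        )
    if len(roots) > 1:
        raise AmbiguousMedianError(roots)
    return roots[0]
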