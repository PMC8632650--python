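"""Dose estimation: inverting a calibration curve with Merkle uncertainty bounds.

Given an observed aberration count in a known number of cells, the point
dose is the non-negative root of C + alpha*D + beta*D^2 = count/cells.
Uncertainty combines the two sources Merkle's procedure intersects:

* the exact (Garwood) confidence interval of the Poisson count, and
* the confidence envelope of the fitted curve, Y(D) +/- z * SE(D), with
  SE(D) propagated from the fit's variance-covariance matrix.

The lower dose bound is where the *upper* curve envelope crosses the lower
count limit; the upper bound is where the *lower* envelope crosses the
upper count limit. Both confidence levels default to 95% (joint coverage
of the resulting dose interval is then at least ~90%). Whole-body acute
exposure is assumed throughout; partial-body corrections are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from scipy import optimize, stats

from .aberration_core import AberrationTally
from .dose_response import (
    DoseResponseCurve,
    endpoint_count,
    exact_poisson_ci,
    yield_at,
    yield_se_at,
)

__all__ = ["DoseEstimate", "invert_curve", "estimate_dose", "dose_from_multiple_endpoints"]

#: Default upper limit (Gy) for root bracketing; beyond the usual
#: calibration range (0-4 Gy for this assay) a warning is attached.
DEFAULT_D_MAX = 10.0


@dataclass(frozen=True)
class DoseEstimate:
    dose_gy: float
    lower_gy: float
    upper_gy: float
    observed_count: int
    n_cells: int
    observed_yield: float
    conf_count: float
    conf_curve: float
    curve_endpoint: str
    upper_open: bool = False  # upper bound hit D_max without a crossing
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower_gy <= self.dose_gy <= self.upper_gy):
            raise ValueError(
                f"bounds must satisfy 0 <= lower <= point <= upper, got "
                f"({self.lower_gy}, {self.dose_gy}, {self.upper_gy})"
            )


def invert_curve(curve: DoseResponseCurve, y: float) -> float:
    """Dose at which the fitted curve reaches per-cell yield ``y``.

    Closed form: the non-negative root of beta*D^2 + alpha*D + (C - y) = 0,
    or the linear inverse when beta = 0. Yields at or below the background
    C map to 0 Gy.
    """
    if y < 0:
        raise ValueError(f"yield must be >= 0, got {y}")
    if curve.alpha < 0 or curve.beta < 0:
        raise ValueError("invert_curve requires alpha, beta >= 0")
    if curve.alpha == 0 and curve.beta == 0:
        raise ValueError("curve has alpha = beta = 0: dose is unidentifiable")
    if y <= curve.C:
        return 0.0
    excess = y - curve.C
    if curve.beta == 0:
        return excess / curve.alpha
    return (-curve.alpha + math.sqrt(curve.alpha**2 + 4.0 * curve.beta * excess)) / (
        2.0 * curve.beta
    )


def _solve_crossing(f, d_max: float) -> float | None:
    """Smallest root of f on [0, d_max], or None if f keeps one sign.

    f is continuous; a sign change over the bracket is located with Brent's
    method after a coarse scan (the envelopes are smooth low-order
    polynomials plus a square root, so 256 panels are ample).
    """
    grid = [d_max * i / 256 for i in range(257)]
    f_prev = f(grid[0])
    if f_prev == 0.0:
        return 0.0
    for d in grid[1:]:
        f_cur = f(d)
        if f_cur == 0.0:
            return d
        if (f_prev < 0) != (f_cur < 0):
            lo = d - d_max / 256
            return float(optimize.brentq(f, lo, d, xtol=1e-10))
        f_prev = f_cur
    return None


def estimate_dose(
    curve: DoseResponseCurve,
    observed_count: int,
    n_cells: int,
    conf_count: float = 0.95,
    conf_curve: float = 0.95,
    d_max: float = DEFAULT_D_MAX,
) -> DoseEstimate:
    """Point dose and Merkle uncertainty bounds for an observed count.

    ``conf_count`` sets the Garwood interval of the count (0 collapses it
    to the observed count, removing that uncertainty source);
    ``conf_curve`` sets the z of the curve envelope (0 collapses the
    envelope onto the fitted curve).
    """
    if observed_count < 0 or n_cells < 1:
        raise ValueError("observed_count must be >= 0 and n_cells >= 1")
    if not (0.0 <= conf_count < 1.0) or not (0.0 <= conf_curve < 1.0):
        raise ValueError("confidence levels must lie in [0, 1)")

    y_obs = observed_count / n_cells
    point = invert_curve(curve, y_obs)
    warnings: list[str] = []
    if point > 4.0:
        warnings.append(
            f"point estimate {point:.3g} Gy lies above the usual 0-4 Gy "
            "calibration range; extrapolation"
        )

    if conf_count == 0.0:
        y_low, y_high = y_obs, y_obs
    else:
        lo_count, hi_count = exact_poisson_ci(observed_count, conf_count)
        y_low, y_high = lo_count / n_cells, hi_count / n_cells

    z = 0.0 if conf_curve == 0.0 else float(stats.norm.ppf(0.5 + conf_curve / 2.0))

    # Lower bound: upper envelope meets the lower count limit.
    upper_env = lambda d: yield_at(curve, d) + z * yield_se_at(curve, d)
    if upper_env(0.0) >= y_low:
        lower = 0.0  # envelope already above the count limit at 0 Gy
    else:
        root = _solve_crossing(lambda d: upper_env(d) - y_low, d_max)
        lower = root if root is not None else 0.0

    # Upper bound: lower envelope meets the upper count limit.
    lower_env = lambda d: yield_at(curve, d) - z * yield_se_at(curve, d)
    upper_open = False
    root = _solve_crossing(lambda d: lower_env(d) - y_high, d_max)
    if root is None:
        upper = d_max
        upper_open = True
        warnings.append(
            f"lower curve envelope never reaches the upper count limit below "
            f"{d_max} Gy; upper bound is open"
        )
    else:
        upper = root

    lower = min(lower, point)
    upper = max(upper, point)
    return DoseEstimate(
        dose_gy=point,
        lower_gy=lower,
        upper_gy=upper,
        observed_count=observed_count,
        n_cells=n_cells,
        observed_yield=y_obs,
        conf_count=conf_count,
        conf_curve=conf_curve,
        curve_endpoint=curve.endpoint,
        upper_open=upper_open,
        warnings=tuple(warnings),
    )


def dose_from_multiple_endpoints(
    curves: Sequence[DoseResponseCurve],
    tally: AberrationTally,
    conf_count: float = 0.95,
    conf_curve: float = 0.95,
) -> list[DoseEstimate]:
    """One dose estimate per calibrated endpoint from a single score tally.

    Each curve's endpoint selects the matching count from the tally
    (dicentrics, dicentrics+rings, or reconstructed DSB).
    """
    return [
        estimate_dose(
            c,
            endpoint_count(tally, c.endpoint),
            tally.n_cells,
            conf_count=conf_count,
            conf_curve=conf_curve,
        )
        for c in curves
    ]
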