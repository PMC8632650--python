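"""Linear-quadratic dose-response calibration under a quasi-Poisson model.

The per-cell aberration yield follows the standard low-LET form

    Y(D) = C + alpha * D + beta * D**2

with C the spontaneous (0 Gy) yield. For a dose point with ``n_cells``
scored cells, the aberration count is modelled as Poisson with mean
``n_cells * Y(D)`` (identity link on the yield, cells scored as exposure).
Coefficients are maximum-likelihood estimates constrained to be
non-negative, the convention for physical yields; standard errors and the
variance-covariance matrix are scaled by a Pearson-based quasi-Poisson
dispersion estimate (floored at 1 so overdispersion can only widen them).

Dispersion diagnostics follow the dicentric-assay convention: the
dispersion index sigma^2/Y (1 under Poisson) and the Papworth u statistic,
with |u| > 1.96 flagging a significant departure from Poisson at the 5%
level.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import xlogy

from .aberration_core import AberrationTally, count_dsb

__all__ = [
    "ENDPOINTS",
    "DosePoint",
    "DoseResponseCurve",
    "DispersionStats",
    "endpoint_count",
    "points_from_tallies",
    "fit_lq",
    "yield_at",
    "yield_se_at",
    "dispersion_stats",
    "exact_poisson_ci",
    "curve_to_json",
    "curve_from_json",
    "curves_summary_frame",
]

ENDPOINTS = ("dicentrics", "dicentrics_rings", "dsb")

#: Convergence control for the likelihood maximization.
MAX_ITERATIONS = 100
LOGLIK_RTOL = 1e-10
#: Parameters within this distance of 0 are treated as clipped at the bound.
BOUNDARY_TOL = 1e-8


@dataclass(frozen=True)
class DosePoint:
    """One calibration point: dose, cells scored, aberrations observed."""

    dose_gy: float
    n_cells: int
    n_aberrations: int

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise ValueError(f"dose_gy must be >= 0, got {self.dose_gy}")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.n_aberrations < 0:
            raise ValueError(f"n_aberrations must be >= 0, got {self.n_aberrations}")


@dataclass(frozen=True)
class DoseResponseCurve:
    """Fitted linear-quadratic yield curve with its uncertainty."""

    endpoint: str
    C: float
    alpha: float
    beta: float
    se_C: float
    se_alpha: float
    se_beta: float
    vcov: np.ndarray  # 3x3 over (C, alpha, beta), dispersion-scaled
    dispersion_scale: float
    n_points: int
    degenerate: bool = False
    converged: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vcov, dtype=float)
        if v.shape != (3, 3):
            raise ValueError("vcov must be a 3x3 matrix over (C, alpha, beta)")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("vcov must be symmetric")
        if np.any(np.diag(v) < -1e-12):
            raise ValueError("vcov diagonal must be non-negative")
        object.__setattr__(self, "vcov", v)

    def alpha_beta_ratio(self) -> float:
        """Dose (Gy) at which linear and quadratic contributions are equal."""
        if self.beta <= 0:
            raise ZeroDivisionError("alpha/beta is undefined when beta is 0")
        return self.alpha / self.beta


@dataclass(frozen=True)
class DispersionStats:
    """Variance-to-mean diagnostics of a per-cell count distribution."""

    n_cells: int
    total_aberrations: int
    mean_y: float
    variance: float
    dispersion_index: float
    u_value: float | None

    @property
    def poisson_rejected(self) -> bool:
        """True when |u| > 1.96 (5% two-sided departure from Poisson)."""
        return self.u_value is not None and abs(self.u_value) > 1.96


def endpoint_count(tally: AberrationTally, endpoint: str) -> int:
    """Aberration count of a tally for one fitted endpoint."""
    if endpoint == "dicentrics":
        return tally.n_dicentric
    if endpoint == "dicentrics_rings":
        return tally.n_dicentric + tally.n_centric_ring
    if endpoint == "dsb":
        return count_dsb(tally).total_dsb
    raise ValueError(f"unknown endpoint {endpoint!r}; expected one of {ENDPOINTS}")


def points_from_tallies(
    tallies: Sequence[AberrationTally], endpoint: str
) -> list[DosePoint]:
    return [
        DosePoint(t.dose_gy, t.n_cells, endpoint_count(t, endpoint)) for t in tallies
    ]


# ---------------------------------------------------------------------------
# Maximum-likelihood fit
# ---------------------------------------------------------------------------


def _design(d: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(d), d, d * d])


def _neg_loglik(theta: np.ndarray, x: np.ndarray, n: np.ndarray, y: np.ndarray):
    """Poisson negative log-likelihood (constants dropped) and gradient.

    mu_i = n_i * (x_i . theta). A zero mean is only admissible with a zero
    count; y>0 at mu=0 yields +inf so the optimizer retreats.
    """
    lam = x @ theta
    mu = n * lam
    if np.any(mu[y > 0] <= 0):
        return np.inf, np.zeros_like(theta)
    nll = float(np.sum(mu) - np.sum(xlogy(y, mu)))
    ratio = np.zeros_like(mu)
    pos = mu > 0
    ratio[pos] = y[pos] / mu[pos]
    grad = x.T @ (n * (1.0 - ratio))
    return nll, grad


def _fisher_information(
    theta: np.ndarray, x: np.ndarray, n: np.ndarray, free: np.ndarray
) -> np.ndarray:
    """Expected information for the free parameters, I_jk = sum n^2 x_j x_k / mu.

    Points with mu = 0 (possible only when C is clipped at 0 and D = 0)
    carry no information about the free slope parameters (their x_j are 0
    there) and are excluded.
    """
    mu = n * (x @ theta)
    pos = mu > 0
    xf = x[np.ix_(pos, free)]
    w = (n[pos] ** 2) / mu[pos]
    return xf.T @ (w[:, None] * xf)


def fit_lq(
    points: Sequence[DosePoint],
    endpoint: str = "dicentrics",
    scale_floor: float = 1.0,
) -> DoseResponseCurve:
    """Fit Y(D) = C + alpha*D + beta*D^2 by constrained Poisson ML.

    The count at each dose point is Poisson with mean
    ``n_cells * Y(dose)``; C, alpha, beta are constrained >= 0 (boundary
    solutions are refit with the clipped coefficients profiled out, and
    their SEs reported as 0). The covariance of the estimates is the
    inverse expected information times the quasi-Poisson scale
    (Pearson chi^2 / df, floored at ``scale_floor``).

    Needs at least three distinct doses. All-zero counts give the
    degenerate flat fit C = alpha = beta = 0, flagged ``degenerate``.
    """
    points = list(points)
    d = np.array([p.dose_gy for p in points], dtype=float)
    n = np.array([p.n_cells for p in points], dtype=float)
    y = np.array([p.n_aberrations for p in points], dtype=float)
    if len(np.unique(d)) < 3:
        raise ValueError(
            f"fit_lq needs >= 3 distinct doses for 3 parameters, got {len(np.unique(d))}"
        )
    x = _design(d)

    if np.all(y == 0):
        return DoseResponseCurve(
            endpoint=endpoint,
            C=0.0, alpha=0.0, beta=0.0,
            se_C=0.0, se_alpha=0.0, se_beta=0.0,
            vcov=np.zeros((3, 3)),
            dispersion_scale=scale_floor,
            n_points=len(points),
            degenerate=True,
        )

    # Weighted least squares on observed yields as a starting point.
    yields = y / n
    theta0, *_ = np.linalg.lstsq(x * np.sqrt(n)[:, None], yields * np.sqrt(n), rcond=None)
    theta0 = np.clip(theta0, 1e-6, None)

    def solve(free: np.ndarray, start: np.ndarray):
        def fun(tf):
            th = np.zeros(3)
            th[free] = tf
            val, grad = _neg_loglik(th, x, n, y)
            return val, grad[free]

        return optimize.minimize(
            fun,
            start[free],
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * int(free.sum()),
            options={"maxiter": MAX_ITERATIONS, "ftol": LOGLIK_RTOL, "gtol": 1e-12},
        )

    def at_first_order_optimum(theta: np.ndarray) -> bool:
        """KKT check: interior gradient ~ 0, boundary gradient >= 0.

        The bounded line search can stop with a pessimistic status flag at
        the exact boundary optimum, so optimality is verified directly.
        """
        val, grad = _neg_loglik(theta, x, n, y)
        if not np.isfinite(val):
            return False
        projected = np.where(theta <= BOUNDARY_TOL, np.minimum(grad, 0.0), grad)
        return float(np.abs(projected).max()) <= 1e-6 * (1.0 + abs(val))

    def polish(theta: np.ndarray, free: np.ndarray) -> np.ndarray:
        """Derivative-free refinement over the free coefficients."""

        def fun(tf):
            th = np.zeros(3)
            th[free] = np.clip(tf, 0.0, None)
            return _neg_loglik(th, x, n, y)[0]

        start = np.where(free, np.maximum(theta, 1e-4), 0.0)
        nm = optimize.minimize(
            fun, start[free], method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 5000, "maxfev": 5000},
        )
        candidate = np.zeros(3)
        candidate[free] = np.clip(nm.x, 0.0, None)
        if _neg_loglik(candidate, x, n, y)[0] <= _neg_loglik(theta, x, n, y)[0]:
            return candidate
        return theta

    # Bounded quasi-Newton solve, then profile refit with boundary
    # coefficients fixed at exactly 0. The solver's own status flag is not
    # trusted: optimality is verified by the KKT condition, and a
    # derivative-free polish rescues premature line-search terminations.
    theta = np.clip(theta0, 0.0, None)
    free = np.ones(3, dtype=bool)
    converged = False
    for _ in range(4):
        res = solve(free, np.where(free, np.maximum(theta, 1e-6), 0.0))
        theta = np.zeros(3)
        theta[free] = res.x
        if not at_first_order_optimum(theta):
            theta = polish(theta, free)
        theta[theta < BOUNDARY_TOL] = 0.0
        new_free = theta > 0
        if not new_free.any():
            free = new_free
            converged = at_first_order_optimum(theta)
            break
        if np.array_equal(new_free, free) and at_first_order_optimum(theta):
            converged = True
            break
        free = new_free
    if not converged:
        converged = at_first_order_optimum(theta)
    if not converged:
        raise RuntimeError(
            "fit_lq did not converge within the iteration cap; "
            f"last parameters (C, alpha, beta) = {tuple(theta)}"
        )

    mu = n * (x @ theta)
    pos = mu > 0
    n_free = int(free.sum())
    df = max(int(pos.sum()) - n_free, 1)
    pearson = float(np.sum((y[pos] - mu[pos]) ** 2 / mu[pos]))
    scale = max(scale_floor, pearson / df)

    vcov = np.zeros((3, 3))
    if n_free:
        info = _fisher_information(theta, x, n, free)
        cov_free = scale * np.linalg.inv(info)
        vcov[np.ix_(free, free)] = cov_free
    ses = np.sqrt(np.clip(np.diag(vcov), 0.0, None))

    return DoseResponseCurve(
        endpoint=endpoint,
        C=float(theta[0]), alpha=float(theta[1]), beta=float(theta[2]),
        se_C=float(ses[0]), se_alpha=float(ses[1]), se_beta=float(ses[2]),
        vcov=vcov,
        dispersion_scale=scale,
        n_points=len(points),
        converged=converged,
    )


def yield_at(curve: DoseResponseCurve, dose_gy: float) -> float:
    """Expected per-cell yield C + alpha*D + beta*D^2 at a dose."""
    if dose_gy < 0:
        raise ValueError(f"dose_gy must be >= 0, got {dose_gy}")
    return curve.C + curve.alpha * dose_gy + curve.beta * dose_gy**2


def yield_se_at(curve: DoseResponseCurve, dose_gy: float) -> float:
    """Delta-method SE of the fitted yield: sqrt(v' Vcov v), v = (1, D, D^2)."""
    if dose_gy < 0:
        raise ValueError(f"dose_gy must be >= 0, got {dose_gy}")
    eigmin = float(np.linalg.eigvalsh(curve.vcov)[0])
    if eigmin < -1e-10 * max(1.0, float(np.abs(curve.vcov).max())):
        raise ValueError("vcov is not positive semi-definite")
    v = np.array([1.0, dose_gy, dose_gy**2])
    return float(np.sqrt(max(v @ curve.vcov @ v, 0.0)))


# ---------------------------------------------------------------------------
# Dispersion diagnostics and exact Poisson intervals
# ---------------------------------------------------------------------------


def dispersion_stats(per_cell_counts: Sequence[int]) -> DispersionStats:
    """Dispersion index sigma^2/Y and Papworth u for per-cell counts.

    u = (sigma^2/ybar - 1) * sqrt((N - 1) / (2 * (1 - 1/X)))

    with N cells and X total aberrations; u is approximately standard
    normal under Poisson sampling. u is undefined (None) for X < 2, where
    the normalization degenerates.
    """
    counts = np.asarray(per_cell_counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("need at least 2 per-cell counts")
    if np.any(counts < 0):
        raise ValueError("per-cell counts must be >= 0")
    n_cells = int(counts.size)
    total = int(counts.sum())
    mean_y = total / n_cells
    variance = float(counts.var(ddof=1))
    dispersion_index = variance / mean_y if mean_y > 0 else 0.0
    if total >= 2:
        u = (dispersion_index - 1.0) * math.sqrt(
            (n_cells - 1) / (2.0 * (1.0 - 1.0 / total))
        )
    else:
        u = None
    return DispersionStats(
        n_cells=n_cells,
        total_aberrations=total,
        mean_y=mean_y,
        variance=variance,
        dispersion_index=dispersion_index,
        u_value=u,
    )


def exact_poisson_ci(x: int, conf: float = 0.95) -> tuple[float, float]:
    """Garwood exact confidence interval for a Poisson count.

    lower = chi2.ppf((1-conf)/2, 2x) / 2 (0 when x = 0),
    upper = chi2.ppf(1 - (1-conf)/2, 2x + 2) / 2.
    """
    if not 0 < conf < 1:
        raise ValueError(f"conf must be in (0, 1), got {conf}")
    if x < 0:
        raise ValueError(f"count must be >= 0, got {x}")
    a = 1.0 - conf
    lower = 0.0 if x == 0 else float(stats.chi2.ppf(a / 2.0, 2 * x) / 2.0)
    upper = float(stats.chi2.ppf(1.0 - a / 2.0, 2 * x + 2) / 2.0)
    return lower, upper


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def curve_to_json(curve: DoseResponseCurve) -> dict:
    """Curve as a plain JSON-ready dict (vcov row-major, 9 values)."""
    try:
        ratio = curve.alpha_beta_ratio()
    except ZeroDivisionError:
        ratio = None
    return {
        "endpoint": curve.endpoint,
        "C": curve.C,
        "alpha": curve.alpha,
        "beta": curve.beta,
        "se_C": curve.se_C,
        "se_alpha": curve.se_alpha,
        "se_beta": curve.se_beta,
        "vcov": [float(v) for v in np.asarray(curve.vcov).ravel()],
        "dispersion_scale": curve.dispersion_scale,
        "alpha_beta_ratio": ratio,
        "n_points": curve.n_points,
        "degenerate": curve.degenerate,
    }


def curve_from_json(payload: dict | str) -> DoseResponseCurve:
    if isinstance(payload, str):
        payload = json.loads(payload)
    return DoseResponseCurve(
        endpoint=payload["endpoint"],
        C=float(payload["C"]),
        alpha=float(payload["alpha"]),
        beta=float(payload["beta"]),
        se_C=float(payload["se_C"]),
        se_alpha=float(payload["se_alpha"]),
        se_beta=float(payload["se_beta"]),
        vcov=np.asarray(payload["vcov"], dtype=float).reshape(3, 3),
        dispersion_scale=float(payload.get("dispersion_scale", 1.0)),
        n_points=int(payload.get("n_points", 0)),
        degenerate=bool(payload.get("degenerate", False)),
    )


def curves_summary_frame(
    curves: Sequence[DoseResponseCurve], group_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Calibration summary table: alpha +/- SE, beta +/- SE, alpha/beta, cov.

    alpha/beta is rounded to two decimals, the customary presentation of
    the curve-shape ratio in calibration reports.
    """
    if group_ids is None:
        group_ids = [""] * len(curves)
    rows = []
    for gid, c in zip(group_ids, curves):
        try:
            ratio = round(c.alpha_beta_ratio(), 2)
        except ZeroDivisionError:
            ratio = float("nan")
        rows.append(
            {
                "group_id": gid,
                "endpoint": c.endpoint,
                "C": c.C,
                "alpha": c.alpha,
                "se_alpha": c.se_alpha,
                "beta": c.beta,
                "se_beta": c.se_beta,
                "alpha_beta_ratio": ratio,
                "cov_alpha_beta": float(c.vcov[1, 2]),
                "dispersion_scale": c.dispersion_scale,
            }
        )
    return pd.DataFrame(rows)
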