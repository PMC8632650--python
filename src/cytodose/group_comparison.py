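"""Between-group comparisons of aberration distributions, rates, and curves.

Three complementary comparisons:

* ``kruskal_wallis`` — rank test on per-cell count distributions at a
  matched dose (distribution-level, no Poisson assumption);
* ``compare_rates`` — exact conditional test of two Poisson rates
  (conditional on the total count, one group's count is binomial with the
  cell-fraction as success probability), which stays exact when one group
  has zero events, as in near-zero background comparisons;
* ``compare_curves`` — Wald chi-square contrast on the fitted (alpha,
  beta) using the pooled variance-covariance matrices, 2 df.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .dose_response import DoseResponseCurve

__all__ = ["ComparisonResult", "kruskal_wallis", "compare_rates", "compare_curves"]


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    group_ids: tuple[str, ...]
    dose_gy: float | None = None
    endpoint: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value must lie in [0, 1], got {self.p_value}")
        if not np.isfinite(self.statistic):
            raise ValueError("statistic must be finite")


def kruskal_wallis(
    samples: Sequence[Sequence[int]],
    group_ids: Sequence[str] | None = None,
    dose_gy: float | None = None,
    endpoint: str | None = None,
) -> ComparisonResult:
    """Kruskal-Wallis H test across per-cell count samples (tie-corrected).

    The p-value uses the chi-square approximation with (groups - 1)
    degrees of freedom. All observations identical across all groups is
    perfect agreement: H = 0, p = 1.
    """
    samples = [np.asarray(s) for s in samples]
    if len(samples) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs at least 2 observations")
    if group_ids is None:
        group_ids = tuple(f"group{i + 1}" for i in range(len(samples)))
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(*samples)
    return ComparisonResult(
        test_name="kruskal_wallis",
        statistic=float(stat),
        p_value=float(p),
        group_ids=tuple(group_ids),
        dose_gy=dose_gy,
        endpoint=endpoint,
    )


def compare_rates(
    count_a: int,
    cells_a: int,
    count_b: int,
    cells_b: int,
    group_ids: tuple[str, str] = ("a", "b"),
    dose_gy: float | None = None,
    endpoint: str | None = None,
    two_sided_method: str = "minlike",
) -> ComparisonResult:
    """Exact conditional test of two Poisson rates.

    Conditional on the total count X_a + X_b, X_a is Binomial(total,
    cells_a / (cells_a + cells_b)) under equal per-cell rates. The
    two-sided p aggregates outcomes by minimum likelihood (default) or by
    doubling the smaller tail (``two_sided_method="doubled"``). The
    reported statistic is the observed count in the first group.
    """
    for name, v in (("count_a", count_a), ("count_b", count_b)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if cells_a <= 0 or cells_b <= 0:
        raise ValueError("cells scored must be > 0 in both groups")
    total = count_a + count_b
    if total == 0:
        p = 1.0
    else:
        frac = cells_a / (cells_a + cells_b)
        if two_sided_method == "minlike":
            p = float(stats.binomtest(count_a, total, frac, alternative="two-sided").pvalue)
        elif two_sided_method == "doubled":
            lower = float(stats.binom.cdf(count_a, total, frac))
            upper = float(stats.binom.sf(count_a - 1, total, frac))
            p = min(1.0, 2.0 * min(lower, upper))
        else:
            raise ValueError(f"unknown two_sided_method {two_sided_method!r}")
    return ComparisonResult(
        test_name="rate_test",
        statistic=float(count_a),
        p_value=p,
        group_ids=tuple(group_ids),
        dose_gy=dose_gy,
        endpoint=endpoint,
    )


def compare_curves(
    curve_a: DoseResponseCurve,
    curve_b: DoseResponseCurve,
    group_ids: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Wald chi-square contrast on (alpha, beta) between two fitted curves.

    Statistic d' (V_a + V_b)^{-1} d with d the coefficient difference and
    V the (alpha, beta) blocks of the dispersion-scaled covariance
    matrices; p from chi-square with 2 df.
    """
    if curve_a.endpoint != curve_b.endpoint:
        raise ValueError(
            f"curves fit different endpoints: {curve_a.endpoint!r} vs {curve_b.endpoint!r}"
        )
    d = np.array([curve_a.alpha - curve_b.alpha, curve_a.beta - curve_b.beta])
    if np.all(d == 0):
        stat = 0.0
    else:
        pooled = np.asarray(curve_a.vcov)[1:, 1:] + np.asarray(curve_b.vcov)[1:, 1:]
        if np.all(pooled == 0):
            raise ValueError("both curves lack a variance-covariance matrix")
        try:
            stat = float(d @ np.linalg.solve(pooled, d))
        except np.linalg.LinAlgError:
            stat = float(d @ np.linalg.pinv(pooled) @ d)
    p = float(stats.chi2.sf(stat, df=2)) if stat > 0 else 1.0
    return ComparisonResult(
        test_name="curve_wald",
        statistic=stat,
        p_value=p,
        group_ids=tuple(group_ids),
        endpoint=curve_a.endpoint,
    )
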