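"""Small-sample rank tests and regression-slope inference.

The treatment comparisons in this workflow involve 3–5 vessels per group,
where the normal approximation to the Mann–Whitney U distribution is
unreliable and the attainable p-values are coarse.  The exact test
enumerates all C(n1+n2, n1) group assignments of the pooled observations
(average ranks under ties), which is cheap up to n1+n2 = 16; larger samples
fall back to the asymptotic test.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class TestMethod(str, enum.Enum):
    EXACT = "exact"
    NORMAL_APPROX = "normal_approx"


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample or slope test.

    statistic is U for rank tests and t for slope tests; p_two_sided is NaN
    when the design cannot support a test (fewer than 3 points for a slope).
    """

    statistic: float
    p_two_sided: float
    n1: int
    n2: int
    method: TestMethod

    def __post_init__(self) -> None:
        if not math.isnan(self.p_two_sided) and not (0.0 <= self.p_two_sided <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_two_sided}")


# Exact enumeration is mandatory at or below this pooled sample size.
EXACT_ENUMERATION_LIMIT = 16


def _u_statistic(ranks_x: np.ndarray, n1: int) -> float:
    return float(ranks_x.sum() - n1 * (n1 + 1) / 2.0)


def mann_whitney_exact(x, y) -> TestResult:
    """Two-sided Mann–Whitney U test, exact by full enumeration.

    Every one of the C(n1+n2, n1) assignments of the pooled, average-ranked
    observations to the first group is enumerated, so ties are handled by
    conditioning on the observed tie pattern.  The two-sided p is
    2×min(one-sided) capped at 1 (no mid-p).  Beyond a pooled size of 16 the
    asymptotic (tie-corrected normal) test is used instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    if n1 + n2 > EXACT_ENUMERATION_LIMIT:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return TestResult(float(res.statistic), float(res.pvalue), n1, n2, TestMethod.NORMAL_APPROX)

    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # average ranks under ties
    u_obs = _u_statistic(ranks[:n1], n1)

    total = math.comb(n1 + n2, n1)
    n_le = 0
    n_ge = 0
    eps = 1e-9
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = _u_statistic(ranks[list(idx)], n1)
        if u <= u_obs + eps:
            n_le += 1
        if u >= u_obs - eps:
            n_ge += 1
    p = min(1.0, 2.0 * min(n_le, n_ge) / total)
    return TestResult(u_obs, p, n1, n2, TestMethod.EXACT)


def slope_test(times, values) -> tuple[float, float, TestResult]:
    """OLS slope with a two-sided t-test of slope = 0.

    Returns (slope, slope_se, TestResult).  With exactly 2 points the slope
    is the finite difference and the p-value is NaN (no residual degrees of
    freedom).  Perfect fits are handled explicitly: zero residuals with a
    nonzero slope give p = 0, a perfectly flat series gives p = 1.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ValueError("times and values differ in length")
    if t.size < 2:
        raise ValueError("slope requires at least 2 points")
    if t.size == 2:
        slope = (y[1] - y[0]) / (t[1] - t[0])
        return float(slope), 0.0, TestResult(math.nan, math.nan, t.size, 0, TestMethod.NORMAL_APPROX)

    res = sps.linregress(t, y)
    slope, se = float(res.slope), float(res.stderr)
    if math.isnan(se):  # perfectly flat series: zero residuals, zero slope
        se = 0.0
    if se == 0.0 or math.isnan(res.pvalue):
        p = 1.0 if slope == 0.0 else 0.0
        tstat = math.inf if slope != 0.0 else 0.0
    else:
        p = float(res.pvalue)
        tstat = slope / se
    return slope, se, TestResult(float(tstat), p, t.size, 0, TestMethod.NORMAL_APPROX)


def pooled_slope_p(series_list) -> float:
    """Slope p-value from one regression over all points of all replicates.

    This is the "whole dataset" significance mode used to gate rate panels:
    the time/concentration points of every replicate vessel enter a single
    OLS fit and the slope t-test p is returned.
    """
    ts = np.concatenate([np.asarray(s.times, dtype=float) for s in series_list])
    ys = np.concatenate([np.asarray(s.concentrations, dtype=float) for s in series_list])
    if ts.size < 3:
        return math.nan
    order = np.argsort(ts, kind="stable")
    _, _, result = slope_test(ts[order], ys[order])
    return result.p_two_sided
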