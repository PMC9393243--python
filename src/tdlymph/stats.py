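"""Group statistics: mean +/- SD summaries and the unequal-variance t-test.

"Student's t-test, two-tailed distribution, two-sample unequal variance"
is the spreadsheet phrasing of the Welch test; it is implemented here with
the explicit Welch statistic and Welch-Satterthwaite degrees of freedom,
with the two-sided p-value from the t distribution. No multiple-testing
correction is applied (the study design tested each variable at a fixed
alpha of 0.05); reports carry the number of tests run so readers can judge
the family-wise picture themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


class StatsError(ValueError):
    pass


@dataclass
class GroupSummary:
    variable: str
    n: int
    mean: float
    sd: float  # n-1 denominator; NaN (flagged) when n == 1
    unit: str = "dimensionless"
    flags: tuple = ()


@dataclass
class TestResult:
    t: float
    df: float
    p: float
    significant: bool  # p < 0.05
    n_x: int
    n_y: int


def summarize(values: Sequence[float], variable: str = "", unit: str = "dimensionless") -> GroupSummary:
    """Sample mean and SD (n-1 denominator) of one group."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise StatsError("need a non-empty 1-D list of values")
    if x.size == 1:
        return GroupSummary(variable, 1, float(x[0]), float("nan"), unit, ("sd-undefined-n1",))
    return GroupSummary(variable, int(x.size), float(np.mean(x)), float(np.std(x, ddof=1)), unit)


def _welch(x: np.ndarray, y: np.ndarray, axis: int = -1) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nx = x.shape[axis]
    ny = y.shape[axis]
    mx = np.mean(x, axis=axis)
    my = np.mean(y, axis=axis)
    vx = np.var(x, ddof=1, axis=axis)
    vy = np.var(y, ddof=1, axis=axis)
    se2 = vx / nx + vy / ny
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mx - my) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    # identical-variance-zero groups: define t=0, p=1 via df -> nx+ny-2
    t = np.where(se2 == 0, 0.0, t)
    df = np.where(se2 == 0, nx + ny - 2, df)
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return t, df, p


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch two-sample t-test, two-sided.

    Both groups need n >= 2. Two identical groups give t = 0, p = 1.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise StatsError("each group needs at least 2 observations for the Welch test")
    t, df, p = _welch(xa, ya)
    p = float(min(p, 1.0))
    return TestResult(
        t=float(t), df=float(df), p=p, significant=bool(p < ALPHA),
        n_x=int(xa.size), n_y=int(ya.size),
    )


def welch_t_test_batch(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch test over the last axis of two replicate matrices.

    Returns (t, df, p) arrays — the workhorse for Monte-Carlo type-I-error
    and power studies.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape[-1] < 2 or ya.shape[-1] < 2:
        raise StatsError("each group needs at least 2 observations for the Welch test")
    return _welch(xa, ya)


def type_i_error_rate(
    n_per_group: int, n_replicates: int, rng: np.random.Generator, alpha: float = ALPHA
) -> float:
    """Monte-Carlo rejection rate when both groups share one normal distribution."""
    x = rng.standard_normal((n_replicates, n_per_group))
    y = rng.standard_normal((n_replicates, n_per_group))
    _, _, p = welch_t_test_batch(x, y)
    return float(np.mean(p < alpha))
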