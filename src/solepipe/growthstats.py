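"""Before/after growth statistics for tank cohorts.

Implements the statistical toolkit used to compare cohort body weights at
the start and end of a culture period: paired t-test within a group,
Welch/pooled two-sample t-test between group increments, and mean +/- SEM
group summaries with the gainer fraction (share of individuals that gained
weight).  The t statistics and their two-sided p-values are computed from
first principles, with the Student-t tail obtained through the regularized
incomplete beta function; no multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc


class DegenerateVarianceError(ValueError):
    """All differences identical: the t statistic is undefined."""


@dataclass(frozen=True)
class PairedTestResult:
    mean_difference: float
    sem_difference: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


@dataclass(frozen=True)
class TwoSampleTestResult:
    mean_difference: float  # mean(a) - mean(b)
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    equal_variance: bool


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sem: float | None  # None for n = 1
    gainer_percent: float  # share of strictly positive values, %, 2 decimals


def student_t_sf2(t: float, df: float) -> float:
    """Two-sided tail probability P(|T| >= |t|) of the Student t distribution.

    Uses the identity P(|T| >= t) = I_{df/(df+t^2)}(df/2, 1/2) with I the
    regularized incomplete beta function.
    """
    if df <= 0:
        raise ValueError(f"degrees of freedom must be positive, got {df}")
    if not math.isfinite(t):
        return 0.0
    x = df / (df + t * t)
    return float(betainc(df / 2.0, 0.5, x))


def paired_ttest(before, after) -> PairedTestResult:
    """Paired-samples Student t-test of after vs before.

    t = mean(d) / (sd(d)/sqrt(n)) with d = after - before and the sample sd
    (ddof 1); df = n - 1; two-sided p-value.
    """
    b = np.asarray(before, dtype=np.float64)
    a = np.asarray(after, dtype=np.float64)
    if b.shape != a.shape or b.ndim != 1:
        raise ValueError(f"before/after must be equal-length 1-D, got {b.shape}, {a.shape}")
    n = b.size
    if n < 2:
        raise ValueError(f"need n >= 2 pairs, got {n}")
    d = a - b
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise DegenerateVarianceError(
            "all paired differences are identical; t statistic undefined"
        )
    mean_d = float(d.mean())
    sem = sd / math.sqrt(n)
    t = mean_d / sem
    df = n - 1
    return PairedTestResult(
        mean_difference=mean_d,
        sem_difference=sem,
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=student_t_sf2(t, df),
    )


def twosample_ttest(a, b, equal_variance: bool = False) -> TwoSampleTestResult:
    """Two-sample t-test of group means (Welch by default).

    With ``equal_variance=True`` the classic pooled-variance variant is
    used; the two agree exactly when group sizes and variances are equal.
    """
    x = np.asarray(a, dtype=np.float64)
    y = np.asarray(b, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    vx, vy = float(x.var(ddof=1)), float(y.var(ddof=1))
    nx, ny = x.size, y.size
    if vx == 0.0 and vy == 0.0:
        if float(x.mean()) == float(y.mean()):
            # identical constant groups: no evidence of difference
            return TwoSampleTestResult(0.0, 0.0, nx + ny - 2, 1.0, equal_variance)
        raise DegenerateVarianceError("zero variance in both groups")
    if equal_variance:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))
        df = nx + ny - 2
    else:
        se = math.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    mean_diff = float(x.mean() - y.mean())
    t = mean_diff / se if se > 0 else 0.0
    p = student_t_sf2(t, df) if se > 0 else 1.0
    return TwoSampleTestResult(mean_diff, t, df, p, equal_variance)


def summarize_group(values) -> GroupSummary:
    """Mean +/- SEM summary plus the gainer percentage.

    ``values`` are weights or weight increments; ``gainer_percent`` is the
    share of strictly positive entries (meaningful for increments), rounded
    to two decimals.  SEM is None for a single observation.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty input")
    n = int(x.size)
    sem = float(x.std(ddof=1) / math.sqrt(n)) if n > 1 else None
    gainers = round(100.0 * float(np.count_nonzero(x > 0)) / n, 2)
    return GroupSummary(n=n, mean=float(x.mean()), sem=sem, gainer_percent=gainers)


# ---------------------------------------------------------------------------
# Cohort-level driver


def analyze_cohort(df: pd.DataFrame, group_col: str = "group") -> dict:
    """Full before/after analysis of a cohort table.

    Expects columns ``weight_t0_kg``, ``weight_t1_kg`` and a group column.
    Per group: t0/t1/increment summaries (kg and percent) and the paired
    t-test; across groups (when exactly two): Welch t-test on increments.
    Returns a JSON-serializable dict.
    """
    required = {group_col, "weight_t0_kg", "weight_t1_kg"}
    if not required.issubset(df.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    out: dict = {"groups": {}}
    deltas: dict[str, np.ndarray] = {}
    for group, sub in df.groupby(group_col, sort=True):
        t0 = sub["weight_t0_kg"].to_numpy(dtype=np.float64)
        t1 = sub["weight_t1_kg"].to_numpy(dtype=np.float64)
        d = t1 - t0
        deltas[str(group)] = d
        entry = {
            "t0": summarize_group(t0).__dict__,
            "t1": summarize_group(t1).__dict__,
            "increment_kg": summarize_group(d).__dict__,
            "increment_percent": summarize_group(100.0 * d / t0).__dict__,
        }
        try:
            pt = paired_ttest(t0, t1)
            entry["paired_test"] = pt.__dict__
        except (DegenerateVarianceError, ValueError) as e:
            entry["paired_test"] = {"error": str(e)}
        out["groups"][str(group)] = entry
    if len(deltas) == 2:
        (ga, da), (gb, db) = sorted(deltas.items())
        ts = twosample_ttest(da, db, equal_variance=False)
        out["increment_comparison"] = {"groups": [ga, gb], **ts.__dict__}
    return out
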