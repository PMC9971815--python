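"""Statistical routing for group comparisons and per-heart aggregation.

The decision tree mirrors common practice in cellular physiology: test each
sample for normality (D'Agostino-Pearson); if both pass, use a t-test (for
unpaired data an F-test of equal variances decides whether Welch's correction
is applied); if not, test the log-transformed values for normality and, when
both pass, run the t-test on logs; otherwise fall back to the nonparametric
Mann-Whitney (unpaired) or Wilcoxon signed-rank (paired) test.  The route
taken is recorded in the result so every reported p-value is reproducible.
All elementary tests delegate to scipy.stats; the bespoke content here is the
routing, the per-heart aggregation (cells averaged within heart, hearts with
fewer than two cells excluded, one-sample t-test on heart means) and the
imaging-time-window restriction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "choose_and_run_test",
    "per_heart_summary",
    "filter_by_time_window",
    "significance_stars",
]

#: minimum sample size for the D'Agostino-Pearson test (scipy requirement)
_MIN_N_NORMALITY = 8


@dataclass
class ComparisonResult:
    test_name: str  # PT | UT | UTWC | MW | WSRT | one-sample t
    p_value: float
    effect_summary: dict
    route: str  # normal | lognormal | neither
    paired: bool
    statistic: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def significance_stars(p: float) -> str:
    for thresh, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < thresh:
            return stars
    return "ns"


def _passes_normality(x: np.ndarray, alpha: float) -> bool:
    if x.size < _MIN_N_NORMALITY:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = sps.normaltest(x)
    return bool(p > alpha)


def _choose_route(a: np.ndarray, b: np.ndarray | None, alpha: float) -> str:
    samples = [a] if b is None else [a, b]
    if all(_passes_normality(s, alpha) for s in samples):
        return "normal"
    if all(np.all(s > 0) for s in samples) and all(
        _passes_normality(np.log(s), alpha) for s in samples
    ):
        return "lognormal"
    return "neither"


def _f_test_unequal_var(a: np.ndarray, b: np.ndarray, alpha: float) -> bool:
    """Two-sided F-test of equal variances; True when variances differ."""
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        return False
    if va >= vb:
        f, dfn, dfd = va / max(vb, np.finfo(float).tiny), a.size - 1, b.size - 1
    else:
        f, dfn, dfd = vb / max(va, np.finfo(float).tiny), b.size - 1, a.size - 1
    p = 2.0 * min(sps.f.sf(f, dfn, dfd), sps.f.cdf(f, dfn, dfd))
    return bool(p < alpha)


def choose_and_run_test(
    a,
    b,
    paired: bool = False,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Route two samples through the normality decision tree and run the test.

    Routes: both samples normal -> t-test (paired PT, or unpaired UT/UTWC with
    Welch's correction when an F-test finds unequal variances); both lognormal
    after log transform -> the same t-tests on logs; otherwise Mann-Whitney
    (MW, unpaired) or Wilcoxon signed-rank (WSRT, paired, zero differences
    dropped per the standard convention).  Samples below the normality-test
    minimum (n < 8) take the nonparametric route with a warning.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if paired and a.size != b.size:
        raise ValueError("paired samples must have equal length")
    if min(a.size, b.size) < 3:
        raise ValueError("each sample must have n >= 3")
    if min(a.size, b.size) < _MIN_N_NORMALITY:
        warnings.warn(
            f"sample below n = {_MIN_N_NORMALITY}; normality untestable, "
            "taking the nonparametric route"
        )

    route = _choose_route(a, b, alpha)
    effect = {
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)),
        "sd_b": float(b.std(ddof=1)),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }

    if route in ("normal", "lognormal"):
        xa, xb = (np.log(a), np.log(b)) if route == "lognormal" else (a, b)
        if paired:
            if np.all(xa - xb == 0):
                # identical paired samples: zero-variance differences, no evidence
                return ComparisonResult("PT", 1.0, effect, route, True, float("nan"))
            stat, p = sps.ttest_rel(xa, xb)
            name = "PT"
        elif _f_test_unequal_var(xa, xb, alpha):
            stat, p = sps.ttest_ind(xa, xb, equal_var=False)
            name = "UTWC"
        else:
            stat, p = sps.ttest_ind(xa, xb, equal_var=True)
            name = "UT"
    elif paired:
        diffs = a - b
        if np.all(diffs == 0):
            # identical paired samples: no evidence of a difference
            return ComparisonResult("WSRT", 1.0, effect, route, True, float("nan"))
        stat, p = sps.wilcoxon(a, b, zero_method="wilcox")
        name = "WSRT"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "MW"

    return ComparisonResult(name, float(p), effect, route, paired, float(stat))


@dataclass
class PerHeartResult:
    heart_means: dict
    excluded_hearts: list
    p_value: float | None
    statistic: float | None
    underpowered: bool


def per_heart_summary(
    values,
    heart_ids,
    min_cells_per_heart: int = 2,
) -> PerHeartResult:
    """Average per-cell values within heart; one-sample t-test of heart means vs 0.

    Hearts contributing fewer than ``min_cells_per_heart`` cells are excluded
    (isolations represented by a single cell carry no within-heart
    information).  With fewer than two qualifying hearts the comparison is
    marked underpowered and no p-value is reported.
    """
    values = np.asarray(values, dtype=np.float64)
    heart_ids = np.asarray(heart_ids)
    if values.size != heart_ids.size:
        raise ValueError("values and heart_ids must have equal length")

    means: dict = {}
    excluded: list = []
    for heart in pd.unique(heart_ids):
        sel = heart_ids == heart
        if sel.sum() < min_cells_per_heart:
            excluded.append(heart)
            continue
        means[heart] = float(values[sel].mean())

    if len(means) < 2:
        return PerHeartResult(means, excluded, None, None, underpowered=True)
    m = np.fromiter(means.values(), dtype=np.float64)
    if np.ptp(m) == 0:
        # zero-variance heart means: t statistic is unbounded; report exact direction
        return PerHeartResult(means, excluded, 0.0 if m[0] != 0 else 1.0, float("inf"), False)
    stat, p = sps.ttest_1samp(m, 0.0)
    return PerHeartResult(means, excluded, float(p), float(stat), underpowered=False)


def filter_by_time_window(
    cells: pd.DataFrame,
    window_min: float,
    time_col: str = "minutes_since_load",
    group_col: str = "ventricle",
    start: float | None = None,
) -> pd.DataFrame:
    """Restrict cells to one imaging-time window of length ``window_min`` minutes.

    Unless ``start`` is given, the window start is scanned over every observed
    imaging time and chosen to maximize the smaller group count within the
    window (so both groups stay represented), tie-broken by total retained
    cells and then by the earliest start.  An empty result is an error.
    """
    if window_min <= 0:
        raise ValueError("window_min must be positive")
    t = cells[time_col].to_numpy(dtype=np.float64)
    if start is not None:
        sel = (t >= start) & (t <= start + window_min)
        subset = cells[sel]
        if subset.empty:
            raise ValueError("no cells inside the requested time window")
        return subset

    groups = cells[group_col].to_numpy()
    labels = pd.unique(groups)
    best = None
    for s in np.sort(np.unique(t)):
        sel = (t >= s) & (t <= s + window_min)
        counts = [int(((groups == g) & sel).sum()) for g in labels]
        key = (min(counts) if len(labels) > 1 else counts[0], int(sel.sum()), -s)
        if best is None or key > best[0]:
            best = (key, sel)
    if best is None or not best[1].any():
        raise ValueError("no cells inside any candidate time window")
    return cells[best[1]]
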