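"""Season-trend decomposition and dated structural-break detection.

Each pixel's monthly index series is modelled, BFAST-style, as

    y(t) = piecewise-linear trend(t)
         + sum_{k<=K} [ a_k sin(2 pi k t / 12) + b_k cos(2 pi k t / 12) ]
         + e(t)

fitted on the observed months only (cloud gaps are simply absent, never
interpolated).  Breakpoints in the trend are found by exact dynamic
programming over admissible positions, minimising the residual sum of
squares of the deseasonalised series for each candidate break count; the
number of breaks is then chosen by an information criterion.  Season and
trend are estimated by alternating the harmonic fit and the trend
segmentation.

Each detected break carries a step magnitude (trend level after minus
before), a sign, and a 95% confidence interval on its date obtained by
RSS inversion: the set of alternative positions for that one break whose
refitted RSS stays within an F-quantile bound of the minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # fallback keeps the module importable without numba
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap(args[0]) if args and callable(args[0]) else wrap

__all__ = [
    "PixelSeries",
    "TrendBreak",
    "SeasonTrendFit",
    "fit_season_trend",
    "detect_breaks",
    "break_confidence_interval",
    "MIN_OBSERVATIONS",
]

MIN_OBSERVATIONS = 24
LWZ_C0 = 0.299
LWZ_EXPONENT = 2.1


@dataclass
class PixelSeries:
    """One pixel's dated index series; months are indices from an epoch."""

    months: np.ndarray
    values: np.ndarray
    index_name: str = "NDVI"
    location: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.months = np.asarray(self.months, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.months.shape != self.values.shape or self.months.ndim != 1:
            raise ValueError("months and values must be congruent 1-D arrays")
        keep = np.isfinite(self.values)
        self.months = self.months[keep]
        self.values = self.values[keep]
        if np.any(np.diff(self.months) <= 0):
            raise ValueError("months must be strictly increasing")

    def __len__(self) -> int:
        return len(self.months)


@dataclass
class TrendBreak:
    """A dated negative/positive step in the trend component."""

    month: int                     # month index of the first post-break regime
    magnitude: float               # trend level after minus before
    ci: tuple[int, int]            # 95% CI on the break month (inclusive)
    obs_index: int                 # index of last pre-break observation
    rss: float
    n_segments: int
    level: float = 0.95

    @property
    def sign(self) -> int:
        return int(np.sign(self.magnitude))

    def __post_init__(self) -> None:
        if not (self.ci[0] <= self.month <= self.ci[1]):
            raise ValueError("confidence interval must contain the break date")
        if not math.isfinite(self.magnitude):
            raise ValueError("break magnitude must be finite")


# ---------------------------------------------------------------------------
# numba kernels: segment costs and the breakpoint DP
# ---------------------------------------------------------------------------

@njit(cache=False)
def _segment_cost_matrix(t, y, min_len):
    """cost[i, j] = RSS of a straight-line fit to points i..j inclusive.

    Computed in O(n^2) from prefix sums; inadmissible (short) segments get
    +inf.  Time values must be distinct.
    """
    n = len(t)
    S1 = np.zeros(n + 1)
    St = np.zeros(n + 1)
    Stt = np.zeros(n + 1)
    Sy = np.zeros(n + 1)
    Sty = np.zeros(n + 1)
    Syy = np.zeros(n + 1)
    for i in range(n):
        S1[i + 1] = S1[i] + 1.0
        St[i + 1] = St[i] + t[i]
        Stt[i + 1] = Stt[i] + t[i] * t[i]
        Sy[i + 1] = Sy[i] + y[i]
        Sty[i + 1] = Sty[i] + t[i] * y[i]
        Syy[i + 1] = Syy[i] + y[i] * y[i]
    cost = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + min_len - 1, n):
            m = S1[j + 1] - S1[i]
            st = St[j + 1] - St[i]
            stt = Stt[j + 1] - Stt[i]
            sy = Sy[j + 1] - Sy[i]
            sty = Sty[j + 1] - Sty[i]
            syy = Syy[j + 1] - Syy[i]
            det = m * stt - st * st
            if det <= 1e-12:
                # duplicate times cannot occur; guard anyway
                cost[i, j] = syy - sy * sy / m
                continue
            b = (m * sty - st * sy) / det
            a = (sy - b * st) / m
            r = syy - 2.0 * a * sy - 2.0 * b * sty + a * a * m \
                + 2.0 * a * b * st + b * b * stt
            cost[i, j] = max(r, 0.0)
    return cost


@njit(cache=False)
def _dp_breakpoints(cost, max_breaks, min_len):
    """Optimal RSS and breakpoints for 0..max_breaks breaks.

    Returns (rss_by_k, bp_by_k) where bp_by_k[k, :k] holds the indices of
    the last observation of each left segment, in increasing order, and
    unused slots are -1.
    """
    n = cost.shape[0]
    K = max_breaks
    F = np.full((K + 1, n), np.inf)
    back = np.full((K + 1, n), -1, dtype=np.int64)
    for j in range(n):
        F[0, j] = cost[0, j]
    for k in range(1, K + 1):
        for j in range((k + 1) * min_len - 1, n):
            best = np.inf
            arg = -1
            for b in range(k * min_len - 1, j - min_len + 1):
                v = F[k - 1, b] + cost[b + 1, j]
                if v < best:
                    best = v
                    arg = b
            F[k, j] = best
            back[k, j] = arg
    rss_by_k = np.full(K + 1, np.inf)
    bp_by_k = np.full((K + 1, max(K, 1)), -1, dtype=np.int64)
    for k in range(K + 1):
        rss_by_k[k] = F[k, n - 1]
        if not np.isfinite(F[k, n - 1]):
            continue
        j = n - 1
        kk = k
        while kk > 0:
            b = back[kk, j]
            bp_by_k[k, kk - 1] = b
            j = b
            kk -= 1
    return rss_by_k, bp_by_k


def exhaustive_breakpoints(t: np.ndarray, y: np.ndarray, n_breaks: int,
                           min_len: int) -> tuple[float, tuple[int, ...]]:
    """Brute-force minimum-RSS breakpoints by enumerating all placements.

    Exponential in ``n_breaks``; intended for small series where it serves
    as an independent check of the dynamic program.
    """
    from itertools import combinations

    cost = np.asarray(_segment_cost_matrix(
        np.asarray(t, dtype=np.float64), np.asarray(y, dtype=np.float64), min_len))
    n = len(t)
    if n_breaks == 0:
        return float(cost[0, n - 1]), ()
    best = (np.inf, ())
    for combo in combinations(range(n - 1), n_breaks):
        rss = 0.0
        start = 0
        ok = True
        for b in combo:
            if b - start + 1 < min_len:
                ok = False
                break
            rss += cost[start, b]
            start = b + 1
        if not ok or n - start < min_len:
            continue
        rss += cost[start, n - 1]
        if rss < best[0]:
            best = (rss, combo)
    return best


# ---------------------------------------------------------------------------
# season-trend fit
# ---------------------------------------------------------------------------

def _harmonic_design(months: np.ndarray, order: int) -> np.ndarray:
    cols = []
    for k in range(1, order + 1):
        w = 2.0 * np.pi * k * months / 12.0
        cols.append(np.sin(w))
        cols.append(np.cos(w))
    return np.column_stack(cols) if cols else np.empty((len(months), 0))


@dataclass
class SeasonTrendFit:
    """Result of the alternating season/trend fit for one series."""

    series: PixelSeries
    harmonic_order: int
    min_len: int
    max_breaks: int
    criterion: str
    season_coef: np.ndarray
    breakpoints: tuple[int, ...]       # indices of last obs of left segments
    segment_coefs: list                # (intercept, slope) per segment
    fitted: np.ndarray
    rss: float
    rss_by_k: np.ndarray
    bp_by_k: np.ndarray
    deseasonalised: np.ndarray
    cost: np.ndarray = field(repr=False, default=None)

    @property
    def n_segments(self) -> int:
        return len(self.breakpoints) + 1

    def segment_bounds(self) -> list[tuple[int, int]]:
        edges = [-1, *self.breakpoints, len(self.series) - 1]
        return [(edges[i] + 1, edges[i + 1]) for i in range(len(edges) - 1)]

    def trend_at(self, seg: int, month: float) -> float:
        a, b = self.segment_coefs[seg]
        return a + b * month

    @property
    def n_params(self) -> int:
        k = len(self.breakpoints)
        return 2 * (k + 1) + k + 2 * self.harmonic_order


def _resolve_min_len(min_segment: float, n: int) -> int:
    if min_segment < 1:
        return max(3, int(np.ceil(min_segment * n)))
    return max(3, int(min_segment))


def _penalty(criterion: str, n_params: int, n: int) -> float:
    if criterion == "bic":
        return n_params * math.log(n)
    if criterion == "lwz":
        return LWZ_C0 * n_params * math.log(n) ** LWZ_EXPONENT
    raise ValueError(f"unknown criterion {criterion!r}")


def _select_k(rss_by_k: np.ndarray, n: int, harmonic_order: int,
              criterion: str) -> int:
    best_k, best_score = 0, np.inf
    eps = 1e-12
    for k, rss in enumerate(rss_by_k):
        if not np.isfinite(rss):
            continue
        n_params = 2 * (k + 1) + k + 2 * harmonic_order
        score = n * math.log(max(rss, eps) / n) + _penalty(criterion, n_params, n)
        if score < best_score - 1e-9:
            best_score, best_k = score, k
    return best_k


def fit_season_trend(series: PixelSeries, harmonic_order: int = 2,
                     min_segment_fraction: float = 8, max_breaks: int = 4,
                     criterion: str = "bic", n_iter: int = 2) -> SeasonTrendFit:
    """Alternating harmonic-season / piecewise-trend fit of one series.

    ``min_segment_fraction`` below 1 is a fraction of the series length;
    values >= 1 are an absolute observation count (default 8 observations,
    so disturbances close to the end of the archive remain datable).
    """
    n = len(series)
    if n < MIN_OBSERVATIONS:
        raise ValueError(
            f"series has {n} observations; at least {MIN_OBSERVATIONS} required")
    t = series.months.astype(np.float64)
    y = series.values
    min_len = _resolve_min_len(min_segment_fraction, n)
    S = _harmonic_design(series.months, harmonic_order)

    # initial joint fit with a single linear trend
    X0 = np.column_stack([np.ones(n), t, S])
    beta, *_ = np.linalg.lstsq(X0, y, rcond=None)
    gamma = beta[2:]

    breakpoints: tuple[int, ...] = ()
    y_d = rss_by_k = bp_by_k = cost = None
    converged = False
    for it in range(max(1, n_iter)):
        y_d = y - (S @ gamma if S.size else 0.0)
        cost = np.asarray(_segment_cost_matrix(t, y_d, min_len))
        rss_by_k, bp_by_k = (np.asarray(a) for a in
                             _dp_breakpoints(cost, max_breaks, min_len))
        k = _select_k(rss_by_k, n, harmonic_order, criterion)
        new_bp = tuple(int(b) for b in bp_by_k[k, :k])
        # with no breaks the season refit reproduces the initial joint OLS,
        # so the first iteration is already the fixed point
        converged = (it > 0 and new_bp == breakpoints) or (it == 0 and not new_bp)
        breakpoints = new_bp
        if converged:
            break
        # refit season given the segmentation, then re-run the DP; when the
        # segmentation is unchanged the previous DP remains valid
        seg_cols = []
        edges = [-1, *new_bp, n - 1]
        for s in range(len(edges) - 1):
            ind = np.zeros(n)
            ind[edges[s] + 1: edges[s + 1] + 1] = 1.0
            seg_cols.extend([ind, ind * t])
        X = np.column_stack([*seg_cols, S]) if S.size else np.column_stack(seg_cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        gamma = beta[len(seg_cols):]
    y_d = y - (S @ gamma if S.size else 0.0)
    if not converged:
        cost = np.asarray(_segment_cost_matrix(t, y_d, min_len))
        rss_by_k, bp_by_k = (np.asarray(a) for a in
                             _dp_breakpoints(cost, max_breaks, min_len))
        k = _select_k(rss_by_k, n, harmonic_order, criterion)
        breakpoints = tuple(int(b) for b in bp_by_k[k, :k])

    seg_coefs = []
    fitted = np.empty(n)
    edges = [-1, *breakpoints, n - 1]
    rss = 0.0
    for s in range(len(edges) - 1):
        lo, hi = edges[s] + 1, edges[s + 1]
        ts, ys = t[lo:hi + 1], y_d[lo:hi + 1]
        A = np.column_stack([np.ones(len(ts)), ts])
        coef, *_ = np.linalg.lstsq(A, ys, rcond=None)
        seg_coefs.append((float(coef[0]), float(coef[1])))
        resid = ys - A @ coef
        rss += float(resid @ resid)
        fitted[lo:hi + 1] = A @ coef + (S[lo:hi + 1] @ gamma if S.size else 0.0)

    return SeasonTrendFit(
        series=series, harmonic_order=harmonic_order, min_len=min_len,
        max_breaks=max_breaks, criterion=criterion, season_coef=gamma,
        breakpoints=breakpoints, segment_coefs=seg_coefs, fitted=fitted,
        rss=rss, rss_by_k=rss_by_k, bp_by_k=bp_by_k,
        deseasonalised=y_d, cost=cost)


# ---------------------------------------------------------------------------
# break extraction and confidence intervals
# ---------------------------------------------------------------------------

def break_confidence_interval(fit: SeasonTrendFit, break_index: int,
                              level: float = 0.95) -> tuple[int, int]:
    """Date CI for one break of the fit by single-repositioning RSS inversion.

    The chosen break is moved over all admissible positions between its
    neighbours (others held fixed) and the CI is the contiguous run of
    positions, containing the estimate, whose RSS satisfies

        RSS(b') <= RSS_min * (1 + F_{level;1,n-p} / (n - p)).

    Returned as an inclusive month-index range; the lower bound is the
    first calendar month after the last pre-break observation, so unobserved
    gap months in which the break may have occurred are covered.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    bps = fit.breakpoints
    if break_index < 0 or break_index >= len(bps):
        raise IndexError("no such break in fit")
    n = len(fit.series)
    cost = fit.cost
    b_hat = bps[break_index]
    left_start = (bps[break_index - 1] + 1) if break_index > 0 else 0
    right_end = (bps[break_index + 1]) if break_index + 1 < len(bps) else n - 1

    lo_b = left_start + fit.min_len - 1
    hi_b = right_end - fit.min_len
    cand = np.arange(lo_b, hi_b + 1)
    rss_move = np.array([cost[left_start, b] + cost[b + 1, right_end] for b in cand])
    base = cost[left_start, b_hat] + cost[b_hat + 1, right_end]
    other = fit.rss - base
    total = other + rss_move

    dof = max(n - fit.n_params, 1)
    fq = stats.f.ppf(level, 1, dof)
    bound = fit.rss * (1.0 + fq / dof) + 1e-12
    inside = total <= bound
    # contiguous run containing the estimate
    pos = int(np.flatnonzero(cand == b_hat)[0])
    lo = pos
    while lo > 0 and inside[lo - 1]:
        lo -= 1
    hi = pos
    while hi < len(cand) - 1 and inside[hi + 1]:
        hi += 1
    months = fit.series.months
    return int(months[cand[lo]]) + 1, int(months[cand[hi] + 1])


def detect_breaks(fit: SeasonTrendFit, max_breaks: int | None = None,
                  level: float = 0.95) -> list[TrendBreak]:
    """Extract dated trend breaks (with magnitudes and CIs) from a fit.

    ``max_breaks`` may restrict the break count below the fit's own; the
    count is re-chosen by the fit's information criterion.  Returns an
    empty list when no break is supported.
    """
    n = len(fit.series)
    if max_breaks is not None and max_breaks < len(fit.breakpoints):
        sub = fit.rss_by_k[: max_breaks + 1]
        k = _select_k(sub, n, fit.harmonic_order, fit.criterion)
        bps = tuple(int(b) for b in fit.bp_by_k[k, :k])
        fit = _refit_to_breakpoints(fit, bps)
    out = []
    months = fit.series.months
    for i, b in enumerate(fit.breakpoints):
        t_after = float(months[b + 1])
        before = fit.trend_at(i, t_after)
        after = fit.trend_at(i + 1, t_after)
        ci = break_confidence_interval(fit, i, level)
        out.append(TrendBreak(
            month=int(months[b + 1]), magnitude=float(after - before),
            ci=ci, obs_index=int(b), rss=fit.rss,
            n_segments=fit.n_segments, level=level))
    return out


def _refit_to_breakpoints(fit: SeasonTrendFit, bps: tuple[int, ...]) -> SeasonTrendFit:
    n = len(fit.series)
    t = fit.series.months.astype(np.float64)
    y_d = fit.deseasonalised
    seg_coefs = []
    fitted = fit.fitted.copy()
    edges = [-1, *bps, n - 1]
    rss = 0.0
    for s in range(len(edges) - 1):
        lo, hi = edges[s] + 1, edges[s + 1]
        A = np.column_stack([np.ones(hi - lo + 1), t[lo:hi + 1]])
        coef, *_ = np.linalg.lstsq(A, y_d[lo:hi + 1], rcond=None)
        seg_coefs.append((float(coef[0]), float(coef[1])))
        resid = y_d[lo:hi + 1] - A @ coef
        rss += float(resid @ resid)
    return SeasonTrendFit(
        series=fit.series, harmonic_order=fit.harmonic_order,
        min_len=fit.min_len, max_breaks=fit.max_breaks,
        criterion=fit.criterion, season_coef=fit.season_coef,
        breakpoints=bps, segment_coefs=seg_coefs, fitted=fitted, rss=rss,
        rss_by_k=fit.rss_by_k, bp_by_k=fit.bp_by_k,
        deseasonalised=y_d, cost=fit.cost)


def detect_breaks_for_series(series: PixelSeries, **kwargs) -> list[TrendBreak]:
    """Convenience: fit then extract breaks; empty list for short series."""
    level = kwargs.pop("level", 0.95)
    fit = fit_season_trend(series, **kwargs)
    return detect_breaks(fit, level=level)
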