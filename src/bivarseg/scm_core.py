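"""Bivariate structural change model (SCM): segment cost and exact DP fit.

The model is piecewise constant in both variables: within segment ``s``
spanning series indices ``[t_s, t_{s+1})``, LRR observations scatter
around a segment mean mu_s and imBAF observations around nu_s.  The fit
quality of a candidate segment is summarised by its residual sums of
squares (RSS) in each variable, combined into a single non-negative
energy through a weighted Minkowski mean of order ``p``::

    delta_s = ( w_r * rss_r^p  +  w_b * beta * rss_b^p )^(1/p)

with weights ``w_r = l_r / (l_r + l_b)`` and ``w_b = l_b / (l_r + l_b)``,
where ``l_r`` and ``l_b`` count the *observed* values of each variable in
the segment (imputed entries carry zero weight).  ``beta`` sets the
relative contribution of the imBAF variable.

Orders ``p < 1`` make a strong fit in a single variable dominate the
combination: a pair of (near-zero, moderate) RSSs scores lower than two
moderate RSSs with the same sum.  Since segmentation *minimises* the total
energy, this promotes the detection of mean shifts that are present in
only one variable -- e.g. a copy-number change between two segments with
the same allelic ratio -- while still pooling evidence for joint shifts.
``p = 1`` reduces to an additive combination of the two RSSs, which
requires single-variable changes to be more extreme before they pay off.

The total cost of a segmentation ``t_1 ... t_{S+1}`` is the sum of its
segment energies, ``G = sum_s delta_s``, minimised exactly by dynamic
programming.  Bounding the maximum segment length ``l`` reduces the DP
from O(n^2) to O(n*l) per segment count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .signal_transform import BivariateSeries

try:  # optional JIT acceleration of the DP inner loops
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

# Segment RSS below this fraction of the segment's sum of squares is treated
# as exact zero: prefix-sum cancellation leaves residues ~1e-12 on constant
# segments, which would otherwise masquerade as fittable signal under the
# log-likelihood (whose delta floor is absolute, not relative).
RSS_REL_TOL = 1e-10

__all__ = [
    "MinkowskiParams",
    "SegmentStats",
    "SegmentationResult",
    "DPConfig",
    "segment_rss",
    "segment_delta",
    "cost_of_segmentation",
    "optimal_segmentation",
]


@dataclass(frozen=True)
class MinkowskiParams:
    """Minkowski order ``p`` and imBAF weight ``beta`` (defaults 1/4 and 1)."""

    p: float = 0.25
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (self.p > 0):
            raise ValueError(f"Minkowski order p must be positive, got {self.p}")
        if not (self.beta > 0):
            raise ValueError(f"beta must be positive, got {self.beta}")


@dataclass
class SegmentStats:
    """Per-segment sufficient statistics over observed values only."""

    start: int
    end: int  # exclusive
    mean_lrr: float
    mean_imbaf: float
    rss_lrr: float
    rss_imbaf: float
    n_lrr: int
    n_imbaf: int

    @property
    def n_probes(self) -> int:
        return self.end - self.start


@dataclass
class SegmentationResult:
    """Optimal tiling of ``[0, n)`` into ``n_segments`` segments."""

    changepoints: np.ndarray  # t_1 ... t_{S+1}, starts with 0, ends with n
    segments: list
    deltas: np.ndarray
    total_cost: float
    n_segments: int

    @property
    def interior_changepoints(self) -> np.ndarray:
        """Change-points excluding the trivial series boundaries 0 and n."""
        return self.changepoints[1:-1]


@dataclass
class DPConfig:
    """Search constraints for the dynamic programme.

    ``max_segment_length`` is the ``l`` of the O(n*l) complexity bound and
    must be at least as long as the longest constant stretch one expects;
    ``max_segments`` bounds the candidate segment counts handed to model
    selection.  A feasible tiling requires
    ``max_segment_length * max_segments >= n``.
    """

    max_segments: int
    max_segment_length: int
    minkowski: MinkowskiParams = field(default_factory=MinkowskiParams)

    def __post_init__(self) -> None:
        if self.max_segments < 1:
            raise ValueError("max_segments must be >= 1")
        if self.max_segment_length < 2:
            raise ValueError("max_segment_length must be >= 2")

    @classmethod
    def default_for(cls, n: int, minkowski: MinkowskiParams | None = None) -> "DPConfig":
        """Defaults scaled to series length: l = min(n, 3000), S = ceil(n/10)."""
        return cls(
            max_segments=max(1, math.ceil(n / 10)),
            max_segment_length=max(2, min(n, 3000)),
            minkowski=minkowski or MinkowskiParams(),
        )


def _prefix_stats(series: BivariateSeries):
    """Cumulative (sum, sum of squares, count) per variable, observed entries only."""
    if series._prefix_cache is not None:
        return series._prefix_cache
    out = []
    for values, mask in (
        (series.lrr, series.lrr_observed),
        (series.imbaf, series.imbaf_observed),
    ):
        v = np.where(mask, values, 0.0).astype(float)
        out.append(np.concatenate(([0.0], np.cumsum(v))))
        out.append(np.concatenate(([0.0], np.cumsum(v * v))))
        out.append(np.concatenate(([0], np.cumsum(mask.astype(np.int64)))))
    series._prefix_cache = tuple(out)
    return series._prefix_cache


def segment_rss(series: BivariateSeries, start: int, end: int) -> SegmentStats:
    """Means and residual sums of squares of ``[start, end)`` in both variables.

    Constant-time via prefix sums.  A variable with no observed values in
    the segment gets mean NaN, RSS 0 and count 0.
    """
    n = series.n
    if not (0 <= start < end <= n):
        raise ValueError(f"invalid segment [{start}, {end}) for series of length {n}")
    s1r, s2r, cr, s1b, s2b, cb = _prefix_stats(series)

    def _one(s1, s2, c):
        cnt = int(c[end] - c[start])
        if cnt == 0:
            return float("nan"), 0.0, 0
        tot = s1[end] - s1[start]
        mean = tot / cnt
        ssq = s2[end] - s2[start]
        rss = ssq - tot * tot / cnt
        if rss < RSS_REL_TOL * ssq:  # cancellation dust on a constant segment
            rss = 0.0
        return mean, rss, cnt

    mean_r, rss_r, n_r = _one(s1r, s2r, cr)
    mean_b, rss_b, n_b = _one(s1b, s2b, cb)
    return SegmentStats(start, end, mean_r, mean_b, rss_r, rss_b, n_r, n_b)


def segment_delta(stats: SegmentStats, params: MinkowskiParams) -> float:
    """Missing-value-weighted Minkowski energy of one segment.

    ``0^p`` is taken as 0 for all ``p > 0``; a variable entirely missing in
    the segment contributes weight 0, so the formula degenerates cleanly to
    the other variable's RSS.  A segment with no observations at all has
    energy 0.
    """
    l_r, l_b = stats.n_lrr, stats.n_imbaf
    tot = l_r + l_b
    if tot == 0:
        return 0.0
    p = params.p
    inner = (l_r / tot) * stats.rss_lrr ** p + (l_b / tot) * params.beta * stats.rss_imbaf ** p
    return inner ** (1.0 / p)


def cost_of_segmentation(series: BivariateSeries, changepoints, params: MinkowskiParams) -> float:
    """Total energy ``G = sum_s delta_s`` of an explicit tiling.

    ``changepoints`` must be ``(t_1 ... t_{S+1})`` with ``t_1 = 0``,
    ``t_{S+1} = n`` and strictly increasing.  This direct evaluator is the
    reference against which the dynamic programme is checked.
    """
    cps = np.asarray(changepoints, dtype=np.int64)
    n = series.n
    if cps.ndim != 1 or len(cps) < 2 or cps[0] != 0 or cps[-1] != n or np.any(np.diff(cps) <= 0):
        raise ValueError(f"changepoints {cps.tolist()} do not tile [0, {n})")
    return float(
        sum(
            segment_delta(segment_rss(series, int(a), int(b)), params)
            for a, b in zip(cps[:-1], cps[1:])
        )
    )


def _dp_fill(s1r, s2r, cr, s1b, s2b, cb, p, beta, max_s, max_len):
    """Fill DP tables: cost[s, j] = min energy of tiling [0, j) into s segments.

    Predecessor ties break toward the smaller (leftmost) index, giving a
    deterministic, lexicographically smallest change-point vector.
    """
    n = len(s1r) - 1
    inf = np.inf
    inv_p = 1.0 / p
    # common orders avoid the generic pow: sqrt is much cheaper
    mode = 0
    if p == 0.25:
        mode = 1
    elif p == 0.5:
        mode = 2
    elif p == 1.0:
        mode = 3
    cost = np.full((max_s + 1, n + 1), inf)
    pred = np.full((max_s + 1, n + 1), -1, dtype=np.int64)
    cost[0, 0] = 0.0
    for s in range(1, max_s + 1):
        jhi = n if s * max_len >= n else s * max_len
        for j in range(s, jhi + 1):
            ilo = j - max_len
            if ilo < s - 1:
                ilo = s - 1
            best = inf
            bi = -1
            for i in range(ilo, j):
                c0 = cost[s - 1, i]
                if c0 == inf:
                    continue
                lr = cr[j] - cr[i]
                lb = cb[j] - cb[i]
                tot = lr + lb
                if tot == 0:
                    d = 0.0
                else:
                    if lr > 0:
                        t1 = s1r[j] - s1r[i]
                        ssq = s2r[j] - s2r[i]
                        rss_r = ssq - t1 * t1 / lr
                        if rss_r < 1e-10 * ssq:  # RSS_REL_TOL; see module constant
                            rss_r = 0.0
                    else:
                        rss_r = 0.0
                    if lb > 0:
                        t1 = s1b[j] - s1b[i]
                        ssq = s2b[j] - s2b[i]
                        rss_b = ssq - t1 * t1 / lb
                        if rss_b < 1e-10 * ssq:
                            rss_b = 0.0
                    else:
                        rss_b = 0.0
                    if mode == 1:
                        inner = (lr / tot) * np.sqrt(np.sqrt(rss_r)) + (lb / tot) * beta * np.sqrt(np.sqrt(rss_b))
                        i2 = inner * inner
                        d = i2 * i2
                    elif mode == 2:
                        inner = (lr / tot) * np.sqrt(rss_r) + (lb / tot) * beta * np.sqrt(rss_b)
                        d = inner * inner
                    elif mode == 3:
                        d = (lr / tot) * rss_r + (lb / tot) * beta * rss_b
                    else:
                        inner = (lr / tot) * rss_r ** p + (lb / tot) * beta * rss_b ** p
                        d = inner ** inv_p
                c = c0 + d
                if c < best:
                    best = c
                    bi = i
            cost[s, j] = best
            pred[s, j] = bi
    return cost, pred


if _njit is not None:
    _dp_fill = _njit(cache=True)(_dp_fill)


def optimal_segmentation(series: BivariateSeries, config: DPConfig) -> list:
    """Exact minimum-cost segmentations for every feasible segment count.

    Returns one :class:`SegmentationResult` per feasible ``S`` in
    ``1..max_segments`` (``S`` is feasible when ``S <= n`` and
    ``S * max_segment_length >= n``), each with the global minimum of
    :func:`cost_of_segmentation` over all tilings into ``S`` segments of
    length at most ``max_segment_length``.  Costs are non-increasing in
    ``S``.
    """
    n = series.n
    if np.isnan(series.lrr).any() or np.isnan(series.imbaf).any():
        raise ValueError("series contains missing values; run impute_constant first")
    if config.max_segment_length * config.max_segments < n:
        raise ValueError(
            f"infeasible DP config: max_segment_length * max_segments = "
            f"{config.max_segment_length * config.max_segments} < n = {n}"
        )
    s1r, s2r, cr, s1b, s2b, cb = _prefix_stats(series)
    cost, pred = _dp_fill(
        s1r, s2r, cr.astype(np.int64), s1b, s2b, cb.astype(np.int64),
        float(config.minkowski.p), float(config.minkowski.beta),
        int(config.max_segments), int(config.max_segment_length),
    )
    results = []
    for S in range(1, config.max_segments + 1):
        if not np.isfinite(cost[S, n]):
            continue
        cps = [n]
        j = n
        for s in range(S, 0, -1):
            j = int(pred[s, j])
            cps.append(j)
        cps = np.array(cps[::-1], dtype=np.int64)
        segments = [segment_rss(series, int(a), int(b)) for a, b in zip(cps[:-1], cps[1:])]
        deltas = np.array([segment_delta(st, config.minkowski) for st in segments])
        results.append(
            SegmentationResult(
                changepoints=cps,
                segments=segments,
                deltas=deltas,
                total_cost=float(deltas.sum()),
                n_segments=S,
            )
        )
    return results
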