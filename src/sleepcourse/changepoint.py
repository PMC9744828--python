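"""Penalized piecewise-linear segmentation of a 1-D signal.

The segmentation objective is the sum of per-segment residual sums of
squares of independent least-squares line fits, plus a fixed penalty
``beta`` for each change point:

    deviation(K) = sum_j SSE_j + beta * K

``optimal_segmentation`` minimizes this exactly over all numbers and
placements of change points via dynamic programming (optimal
partitioning); ``brute_force_segmentation`` is an exhaustive oracle for
short signals.

Conventions
-----------
* Segments are half-open index ranges ``[start, end)`` that tile the
  signal; a change point at index ``i`` (reported as ``positions[i]``)
  separates segments ``[.., i)`` and ``[i, ..)``.
* Segments fit independently: discontinuities are allowed at breaks.
* Ties in deviation (within ``1e-9``) are broken by preferring fewer
  change points, then the lexicographically smallest change-point
  positions.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._exceptions import DataError

_TIE_TOL = 1e-9

__all__ = [
    "Signal",
    "SegmentFit",
    "SegmentationResult",
    "SweepResult",
    "segment_sse",
    "optimal_segmentation",
    "brute_force_segmentation",
    "threshold_sweep",
]


@dataclass(frozen=True)
class Signal:
    """An ordered 1-D signal: strictly increasing positions with one value each."""

    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.ndim != 1 or val.ndim != 1 or pos.shape != val.shape:
            raise DataError("positions and values must be 1-D arrays of equal length")
        if pos.size < 2:
            raise DataError("signal must contain at least 2 points")
        if not np.all(np.isfinite(pos)) or not np.all(np.isfinite(val)):
            raise DataError("signal contains non-finite entries")
        if not np.all(np.diff(pos) > 0):
            raise DataError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class SegmentFit:
    """Least-squares line fit over the half-open index range [start, end)."""

    start_index: int
    end_index: int
    slope: float
    intercept: float
    sse: float


@dataclass(frozen=True)
class SegmentationResult:
    changepoints: tuple[float, ...]
    changepoint_indices: tuple[int, ...]
    segments: tuple[SegmentFit, ...]
    total_sse: float
    penalty_beta: float
    deviation: float

    @property
    def n_changepoints(self) -> int:
        return len(self.changepoints)

    def to_dict(self) -> dict:
        return {
            "changepoints": list(self.changepoints),
            "changepoint_indices": list(self.changepoint_indices),
            "segments": [
                {
                    "start_index": s.start_index,
                    "end_index": s.end_index,
                    "slope": s.slope,
                    "intercept": s.intercept,
                    "sse": s.sse,
                }
                for s in self.segments
            ],
            "total_sse": self.total_sse,
            "penalty_beta": self.penalty_beta,
            "deviation": self.deviation,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


class _CostCache:
    """O(1) per-segment least-squares costs via prefix sums.

    Positions and values are centered globally before accumulating, which
    keeps the cancellation error in the residual formula well below the
    1e-9 tie tolerance for signals on the scales used here.
    """

    def __init__(self, signal: Signal):
        p = signal.positions - signal.positions.mean()
        v = signal.values - signal.values.mean()
        z = np.zeros(1)
        self._sp = np.concatenate([z, np.cumsum(p)])
        self._spp = np.concatenate([z, np.cumsum(p * p)])
        self._sv = np.concatenate([z, np.cumsum(v)])
        self._svv = np.concatenate([z, np.cumsum(v * v)])
        self._spv = np.concatenate([z, np.cumsum(p * v)])
        self._p_shift = signal.positions.mean()
        self._v_shift = signal.values.mean()

    def _moments(self, i: int, j: int):
        m = j - i
        sp = self._sp[j] - self._sp[i]
        sv = self._sv[j] - self._sv[i]
        sxx = (self._spp[j] - self._spp[i]) - sp * sp / m
        sxy = (self._spv[j] - self._spv[i]) - sp * sv / m
        syy = (self._svv[j] - self._svv[i]) - sv * sv / m
        return m, sp, sv, sxx, sxy, syy

    def sse(self, i: int, j: int) -> float:
        m, _, _, sxx, sxy, syy = self._moments(i, j)
        if m <= 2 or sxx <= 0:
            return 0.0
        return float(max(syy - sxy * sxy / sxx, 0.0))

    def fit(self, i: int, j: int) -> SegmentFit:
        m, sp, sv, sxx, sxy, syy = self._moments(i, j)
        if m == 1 or sxx <= 0:
            slope = 0.0
        else:
            slope = sxy / sxx
        # intercepts reported in the original (uncentered) coordinates
        mean_p = sp / m + self._p_shift
        mean_v = sv / m + self._v_shift
        intercept = mean_v - slope * mean_p
        if m <= 2 or sxx <= 0:
            sse = 0.0
        else:
            sse = float(max(syy - sxy * sxy / sxx, 0.0))
        return SegmentFit(i, j, float(slope), float(intercept), sse)


def segment_sse(signal: Signal, start: int, end: int) -> float:
    """Residual sum of squares of the least-squares line over ``[start, end)``.

    Exact least squares; 0 for segments of one or two points or exactly
    collinear values.
    """
    n = len(signal)
    if not (0 <= start < end <= n):
        raise DataError(f"invalid slice [{start}, {end}) for signal of length {n}")
    return _CostCache(signal).sse(start, end)


def _better(dev_a: float, cps_a: tuple, dev_b: float, cps_b: tuple) -> bool:
    """True if solution a beats b under (deviation, K, lexicographic) order."""
    if dev_a < dev_b - _TIE_TOL:
        return True
    if dev_a > dev_b + _TIE_TOL:
        return False
    if len(cps_a) != len(cps_b):
        return len(cps_a) < len(cps_b)
    return cps_a < cps_b


def _build_result(signal: Signal, cache: _CostCache, boundaries: Sequence[int],
                  beta: float) -> SegmentationResult:
    """Assemble a SegmentationResult from interior boundary indices."""
    n = len(signal)
    edges = [0, *boundaries, n]
    segments = tuple(cache.fit(a, b) for a, b in zip(edges[:-1], edges[1:]))
    total_sse = float(sum(s.sse for s in segments))
    k = len(boundaries)
    return SegmentationResult(
        changepoints=tuple(float(signal.positions[i]) for i in boundaries),
        changepoint_indices=tuple(int(i) for i in boundaries),
        segments=segments,
        total_sse=total_sse,
        penalty_beta=float(beta),
        deviation=total_sse + float(beta) * k,
    )


def optimal_segmentation(signal: Signal, beta: float) -> SegmentationResult:
    """Global minimizer of the penalized deviation over all segmentations.

    Dynamic programming over prefixes (optimal partitioning); provably
    equal to exhaustive enumeration over all interior boundary subsets.
    """
    if beta < 0:
        raise DataError("beta must be >= 0")
    n = len(signal)  # Signal validates n >= 2
    cache = _CostCache(signal)

    # best[j]: (deviation, boundary index tuple) for optimal segmentation
    # of the prefix [0, j). A segment start at i > 0 contributes one beta.
    best_dev = [0.0] * (n + 1)
    best_cps: list[tuple[int, ...]] = [()] * (n + 1)
    for j in range(1, n + 1):
        cur_dev = np.inf
        cur_cps: tuple[int, ...] = ()
        for i in range(j):
            cand_dev = best_dev[i] + cache.sse(i, j) + (beta if i > 0 else 0.0)
            cand_cps = best_cps[i] + ((i,) if i > 0 else ())
            if _better(cand_dev, cand_cps, cur_dev, cur_cps):
                cur_dev, cur_cps = cand_dev, cand_cps
        best_dev[j] = cur_dev
        best_cps[j] = cur_cps
    return _build_result(signal, cache, best_cps[n], beta)


def brute_force_segmentation(signal: Signal, beta: float) -> SegmentationResult:
    """Exhaustive-enumeration oracle: minimal deviation over every subset of
    interior boundary indices, tie-broken identically to
    :func:`optimal_segmentation`. Refuses signals longer than 16 points.
    """
    if beta < 0:
        raise DataError("beta must be >= 0")
    n = len(signal)
    if n > 16:
        raise DataError("brute force is limited to signals of length <= 16")
    cache = _CostCache(signal)
    interior = range(1, n)

    best_dev = np.inf
    best_cps: tuple[int, ...] | None = None
    # iterate K ascending, combinations in lexicographic order: keeping only
    # strict improvements reproduces the (deviation, K, lex) tie-break
    for k in range(0, n):
        for cps in itertools.combinations(interior, k):
            edges = (0, *cps, n)
            dev = 0.0
            for a, b in zip(edges[:-1], edges[1:]):
                if a > 0:
                    dev += beta
                dev += cache.sse(a, b)
            if dev < best_dev - _TIE_TOL:
                best_dev = dev
                best_cps = cps
    assert best_cps is not None
    return _build_result(signal, cache, best_cps, beta)


@dataclass(frozen=True)
class SweepResult:
    """Change-point sets across a sweep of penalty thresholds."""

    by_threshold: Mapping[float, tuple[float, ...]] = field(default_factory=dict)

    def stable_ranges(self) -> list[tuple[float, float, tuple[float, ...]]]:
        """Contiguous threshold ranges over which the change-point set is
        constant, as (t_min, t_max, changepoints) in ascending order."""
        ranges: list[tuple[float, float, tuple[float, ...]]] = []
        for t in sorted(self.by_threshold):
            cps = self.by_threshold[t]
            if ranges and ranges[-1][2] == cps:
                ranges[-1] = (ranges[-1][0], t, cps)
            else:
                ranges.append((t, t, cps))
        return ranges

    def widest_stable_set(self) -> tuple[float, ...]:
        """Change-point set stable over the widest contiguous threshold range."""
        ranges = self.stable_ranges()
        widths = [(hi - lo, -i) for i, (lo, hi, _) in enumerate(ranges)]
        best = max(range(len(ranges)), key=lambda i: widths[i])
        return ranges[best][2]


def threshold_sweep(signal: Signal, t_values: Iterable[float]) -> SweepResult:
    """One optimal segmentation per threshold, with ``beta = T``."""
    ts = [float(t) for t in t_values]
    if not ts:
        raise DataError("t_values must be non-empty")
    if any(t <= 0 for t in ts if np.isfinite(t)):
        raise DataError("thresholds must be positive")
    if sorted(ts) != ts:
        raise DataError("t_values must be sorted ascending")
    out: dict[float, tuple[float, ...]] = {}
    for t in ts:
        if np.isinf(t):
            out[t] = ()
        else:
            out[t] = optimal_segmentation(signal, t).changepoints
    return SweepResult(by_threshold=out)
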