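"""Training (TP) and wayfinding (WF) performance from raw trajectories.

The wayfinding metric is the first principal component of the per-level
trajectory lengths of the four wayfinding levels, each divided by the
summed length of the two tutorial levels (controlling for device
familiarity); the training metric is built the same way from the raw
tutorial lengths. Both composites are negated (shorter path = better),
offset so the worst pre-z score is 0, and z-scored over the scored
population (mean 0, SD 1; higher = better).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, DataError, DegenerateDataError

__all__ = [
    "Trajectory",
    "PerformanceScore",
    "trajectory_length",
    "normalize_lengths",
    "first_pc_scores",
    "compose_performance",
    "compute_tp_wf",
]


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped 2-D path for one participant x level."""

    participant_id: str
    level: int
    tutorial: bool
    t_ms: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_ms, dtype=np.int64)
        xy = np.asarray(self.xy, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise DataError("trajectory needs >= 1 sample")
        if xy.shape != (t.size, 2):
            raise DataError("xy must be an (n, 2) array matching t_ms")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise DataError("timestamps must be strictly increasing")
        object.__setattr__(self, "t_ms", t)
        object.__setattr__(self, "xy", xy)


@dataclass(frozen=True)
class PerformanceScore:
    participant_id: str
    tp: float
    wf: float


def trajectory_length(traj: Trajectory) -> float:
    """Sum of Euclidean distances between consecutive samples (pixels)."""
    if len(traj.xy) < 2:
        return 0.0
    return float(np.hypot(*np.diff(traj.xy, axis=0).T).sum())


def normalize_lengths(
    lengths_by_level: Mapping[int, float],
    tutorial_levels: Sequence[int],
    wayfinding_levels: Sequence[int],
) -> dict[int, float]:
    """Divide each wayfinding length by the summed tutorial length.

    Raises :class:`DataError` when a required level is missing or the
    tutorial sum is not positive (the caller excludes the participant).
    """
    missing = [lv for lv in (*tutorial_levels, *wayfinding_levels)
               if lv not in lengths_by_level]
    if missing:
        raise DataError(f"missing levels: {missing}")
    tut_sum = float(sum(lengths_by_level[lv] for lv in tutorial_levels))
    if tut_sum <= 0:
        raise DataError("tutorial length sum is not positive")
    return {lv: float(lengths_by_level[lv]) / tut_sum for lv in wayfinding_levels}


def first_pc_scores(matrix: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Project rows onto the leading eigenvector of the column covariance.

    Returns ``(scores, variance_explained, loadings)``. The sign is fixed
    so the loadings on the length columns are non-negative (all loadings
    when possible, otherwise their sum), so the score increases with
    trajectory length.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise DataError("need a 2-D matrix with >= 2 rows and >= 2 columns")
    if not np.all(np.isfinite(x)):
        raise DataError("matrix contains non-finite values")
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 0:
        raise DegenerateDataError("matrix has rank 0 after centering")
    loadings = vt[0]
    if np.all(loadings <= 0) or loadings.sum() < 0:
        loadings = -loadings
    scores = centered @ loadings
    var_explained = float(s[0] ** 2 / np.sum(s ** 2))
    return scores, var_explained, loadings


def compose_performance(raw_scores: np.ndarray) -> np.ndarray:
    """Negate, offset so the worst pre-z score is 0, then z-score.

    Raw scores increase with trajectory length, so after negation higher
    means better. The z-score uses the population SD (ddof=0) over the
    scored set: the output has mean 0 and SD 1 exactly.
    """
    x = np.asarray(raw_scores, dtype=float)
    if x.size < 2:
        raise DataError("need >= 2 scores")
    inverted = -x
    shifted = inverted - inverted.min()
    sd = shifted.std(ddof=0)
    if sd == 0:
        raise DegenerateDataError("scores have zero variance")
    return (shifted - shifted.mean()) / sd


def _level_length_table(trajectories: Iterable[Trajectory]) -> tuple[pd.DataFrame, int]:
    """Per (participant, level) raw lengths; duplicates beyond the first
    attempt are dropped with a warning."""
    rows = [(t.participant_id, t.level, t.tutorial, trajectory_length(t))
            for t in trajectories]
    df = pd.DataFrame(rows, columns=["participant_id", "level", "tutorial", "length"])
    before = len(df)
    df = df.drop_duplicates(subset=["participant_id", "level"], keep="first")
    n_dup = before - len(df)
    if n_dup:
        warnings.warn(f"dropped {n_dup} repeated (participant, level) attempts; "
                      "only first attempts are scored", stacklevel=3)
    return df, n_dup


def compute_tp_wf(
    trajectories: Iterable[Trajectory],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every participant with complete level sets.

    Returns ``(scores, exclusions)``: scores has columns participant_id,
    tp, wf, n_levels_used; exclusions has participant_id, excluded_reason.
    """
    table, _ = _level_length_table(trajectories)
    if table.empty:
        raise DataError("no trajectories provided")
    tutorial_levels = sorted(table.loc[table["tutorial"], "level"].unique())
    wayfinding_levels = sorted(table.loc[~table["tutorial"], "level"].unique())
    if len(tutorial_levels) != 2:
        raise ConfigError(f"expected exactly 2 tutorial levels, got {tutorial_levels}")
    if len(wayfinding_levels) < 1:
        raise ConfigError("no wayfinding levels present")

    wide = table.pivot(index="participant_id", columns="level", values="length")
    excl: list[tuple[str, str]] = []
    required = [*tutorial_levels, *wayfinding_levels]
    complete = wide[required].notna().all(axis=1)
    for pid in wide.index[~complete]:
        missing = [lv for lv in required if pd.isna(wide.at[pid, lv])]
        excl.append((pid, f"missing levels {missing}"))
    wide = wide[complete]

    tut_sum = wide[tutorial_levels].sum(axis=1)
    bad_tut = tut_sum <= 0
    for pid in wide.index[bad_tut]:
        excl.append((pid, "tutorial length sum is not positive"))
    wide = wide[~bad_tut]
    tut_sum = tut_sum[~bad_tut]

    if len(wide) < 2:
        raise DataError("fewer than 2 scorable participants")

    wf_matrix = wide[wayfinding_levels].div(tut_sum, axis=0).to_numpy()
    tp_matrix = wide[tutorial_levels].to_numpy()
    wf_raw, _, _ = first_pc_scores(wf_matrix)
    tp_raw, _, _ = first_pc_scores(tp_matrix)
    scores = pd.DataFrame({
        "participant_id": wide.index,
        "tp": compose_performance(tp_raw),
        "wf": compose_performance(wf_raw),
        "n_levels_used": len(required),
    }).reset_index(drop=True)
    exclusions = pd.DataFrame(excl, columns=["participant_id", "excluded_reason"])
    return scores, exclusions
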