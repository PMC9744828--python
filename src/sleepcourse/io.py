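"""Plain-text readers and writers for the package's external formats.

Cohort CSV: participant_id, age, gender, education, home_env, commute,
country, sleep_hours. Trajectory CSV/JSONL: participant_id, level, t_ms,
x, y sorted by (participant_id, level, t_ms); the tutorial flag is carried
in a ``tutorial`` column. Signals are two-column position,value CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._exceptions import DataError
from .changepoint import Signal
from .navigation import Trajectory

COHORT_COLUMNS = ["participant_id", "age", "gender", "education", "home_env",
                  "commute", "country", "sleep_hours"]


def write_cohort_csv(records: pd.DataFrame, path: str | Path) -> None:
    records[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"cohort CSV missing columns: {missing}")
    return df


def _trajectory_frame(trajectories: Iterable[Trajectory]) -> pd.DataFrame:
    parts = []
    for t in trajectories:
        parts.append(pd.DataFrame({
            "participant_id": t.participant_id,
            "level": t.level,
            "tutorial": t.tutorial,
            "t_ms": t.t_ms,
            "x": t.xy[:, 0],
            "y": t.xy[:, 1],
        }))
    if not parts:
        return pd.DataFrame(columns=["participant_id", "level", "tutorial",
                                     "t_ms", "x", "y"])
    df = pd.concat(parts, ignore_index=True)
    return df.sort_values(["participant_id", "level", "t_ms"], kind="stable")


def write_trajectories_csv(trajectories: Iterable[Trajectory], path: str | Path) -> None:
    _trajectory_frame(trajectories).to_csv(path, index=False)


def write_trajectories_jsonl(trajectories: Iterable[Trajectory], path: str | Path) -> None:
    df = _trajectory_frame(trajectories)
    with open(path, "w", encoding="utf-8") as fh:
        for row in df.itertuples(index=False):
            fh.write(json.dumps(row._asdict()) + "\n")


def _frame_to_trajectories(df: pd.DataFrame) -> list[Trajectory]:
    out = []
    for (pid, level), sub in df.groupby(["participant_id", "level"], sort=True):
        sub = sub.sort_values("t_ms", kind="stable")
        out.append(Trajectory(
            participant_id=str(pid),
            level=int(level),
            tutorial=bool(sub["tutorial"].iloc[0]),
            t_ms=sub["t_ms"].to_numpy(),
            xy=sub[["x", "y"]].to_numpy(dtype=float),
        ))
    return out


def read_trajectories_csv(path: str | Path) -> list[Trajectory]:
    return _frame_to_trajectories(pd.read_csv(path))


def read_trajectories_jsonl(path: str | Path) -> list[Trajectory]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rows.append(json.loads(line))
    if not rows:
        return []
    return _frame_to_trajectories(pd.DataFrame(rows))


def read_signal_csv(path: str | Path) -> Signal:
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise DataError("signal CSV needs two columns: position,value")
    return Signal(positions=df.iloc[:, 0].to_numpy(dtype=float),
                  values=df.iloc[:, 1].to_numpy(dtype=float))


def write_signal_csv(signal: Signal, path: str | Path,
                     names: Sequence[str] = ("position", "value")) -> None:
    pd.DataFrame({names[0]: signal.positions,
                  names[1]: signal.values}).to_csv(path, index=False)
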