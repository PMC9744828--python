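"""Synthetic cohort and trajectory generator with known ground truth.

Every downstream stage (filtering, age curves, change-point detection,
navigation metrics, mixed models, cluster tests) is exercised against data
produced here, so the generator emulates the statistical structure the
analysis targets:

* a three-phase piecewise-linear mean-sleep-vs-age trend with change
  points near 33 and 53 years,
* a gender offset (women - men ~ +0.13 h), country-level random
  intercepts and optional supra-national cluster mean shifts,
* integer-hour sleep reporting with a small out-of-range tail so the
  inclusion filter has work to do,
* latent navigation and motor skills, with an inverted-U quadratic link
  between reported sleep and navigation skill (peak at 7 h) concentrated
  in the oldest age group,
* 2-D game trajectories whose wayfinding path length increases in
  expectation as navigation skill decreases, while tutorial path length
  depends only on motor skill.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._exceptions import ConfigError
from ._util import AGE_GROUP_LABELS, assign_age_groups
from .navigation import Trajectory

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "LevelSpec",
    "TrajectoryConfig",
    "generate_cohort",
    "generate_trajectories",
    "piecewise_trend",
    "default_level_specs",
]

GENDERS = ("man", "woman")
EDUCATION = ("secondary", "tertiary")
HOME_ENV = ("city", "non-city")
COMMUTE = ("<30min", "30-60min", ">60min")

_DEFAULT_CLUSTERS = ("G1", "G2", "G3", "G4", "G5", "G6", "G7")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the cohort generator.

    ``residual_sd`` defaults to 1.05, which (together with integer
    rounding, country intercepts and the gender offset) puts the marginal
    SD of included sleep reports at ~1.07 h, with ~1% of reports falling
    outside the 5-10 h inclusion range.
    """

    n_participants: int = 10_000
    age_range: tuple[int, int] = (19, 70)
    true_changepoints: tuple[float, ...] = (33.0, 53.0)
    phase_slopes: tuple[float, ...] = (-0.025, -0.005, 0.012)
    intercept_at_min_age: float = 7.35
    gender_offset: float = 0.13
    n_countries: int = 30
    country_intercept_sd: float = 0.2
    residual_sd: float = 1.05
    round_to_hours: bool = True
    sleep_support: tuple[int, int] = (1, 14)
    cluster_labels: tuple[str, ...] = _DEFAULT_CLUSTERS
    cluster_assignment: Mapping[str, str] | None = None
    cluster_shifts: Mapping[str, float] | None = None
    weird_flags: Mapping[str, bool] | None = None
    latitude_effect: float = 0.0
    gdp_effect: float = 0.0
    skill_link: Mapping[str, tuple[float, float]] | None = None
    nav_skill_base: float = 0.70
    nav_skill_sd: float = 0.12
    motor_skill_base: float = 0.60
    motor_skill_sd: float = 0.15
    age_weights: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        lo, hi = self.age_range
        if lo >= hi:
            raise ConfigError("age_range must be ordered")
        cps = tuple(float(c) for c in self.true_changepoints)
        if len(self.phase_slopes) != len(cps) + 1:
            raise ConfigError(
                f"{len(cps)} change points require {len(cps) + 1} phase slopes, "
                f"got {len(self.phase_slopes)}"
            )
        if any(b >= c for b, c in zip(cps, cps[1:])):
            raise ConfigError("change points must be strictly increasing")
        if cps and (cps[0] <= lo or cps[-1] >= hi):
            raise ConfigError("change points must be interior to age_range")
        if self.residual_sd < 0:
            raise ConfigError("residual_sd must be >= 0")
        if self.n_countries < 1:
            raise ConfigError("n_countries must be >= 1")
        if self.age_weights is not None and len(self.age_weights) != hi - lo + 1:
            raise ConfigError("age_weights must have one entry per age in range")

    @property
    def country_codes(self) -> tuple[str, ...]:
        return tuple(f"K{i:02d}" for i in range(1, self.n_countries + 1))

    def resolved_clusters(self) -> dict[str, str]:
        """Country -> cluster map (round-robin over cluster_labels by default)."""
        if self.cluster_assignment is not None:
            out = dict(self.cluster_assignment)
            missing = [c for c in self.country_codes if c not in out]
            if missing:
                raise ConfigError(f"cluster_assignment missing countries: {missing}")
            return out
        labels = self.cluster_labels
        return {c: labels[i % len(labels)] for i, c in enumerate(self.country_codes)}

    def resolved_weird(self) -> dict[str, bool]:
        if self.weird_flags is not None:
            return {c: bool(self.weird_flags.get(c, False)) for c in self.country_codes}
        cut = max(1, self.n_countries // 3)
        return {c: i < cut for i, c in enumerate(self.country_codes)}

    def resolved_skill_link(self) -> dict[str, tuple[float, float]]:
        """Age-group -> (linear, quadratic) coefficients of the sleep->skill
        link, in skill units per hour around 7 h. Default: inverted-U in the
        oldest group only, peaking at 7 h."""
        if self.skill_link is not None:
            out = {g: (float(a), float(b)) for g, (a, b) in self.skill_link.items()}
            for g in AGE_GROUP_LABELS:
                out.setdefault(g, (0.0, 0.0))
            return out
        return {"young": (0.0, 0.0), "middle": (0.0, 0.0), "older": (0.0, -0.03)}


def piecewise_trend(ages, config: CohortConfig) -> np.ndarray:
    """Continuous piecewise-linear mean sleep (hours) at each age."""
    ages = np.asarray(ages, dtype=float)
    lo, hi = config.age_range
    knots = [float(lo), *config.true_changepoints, float(hi)]
    out = np.full(ages.shape, config.intercept_at_min_age, dtype=float)
    for slope, a, b in zip(config.phase_slopes, knots[:-1], knots[1:]):
        out += slope * np.clip(ages - a, 0.0, b - a)
    return out


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    true_changepoints: tuple[float, ...]
    gender_offset: float
    country_table: pd.DataFrame  # country, intercept, effective_intercept,
    #                              cluster, weird, abs_latitude, gdp_per_capita
    skill_link: dict[str, tuple[float, float]]
    nav_skill: pd.Series  # indexed by participant_id
    motor_skill: pd.Series
    config: CohortConfig | None = None

    @property
    def country_intercepts(self) -> pd.Series:
        return self.country_table.set_index("country")["intercept"]

    def to_json(self, **kwargs) -> str:
        payload = {
            "true_changepoints": list(self.true_changepoints),
            "gender_offset": self.gender_offset,
            "country_table": self.country_table.to_dict(orient="list"),
            "skill_link": {g: list(v) for g, v in self.skill_link.items()},
            "nav_skill": {"index": self.nav_skill.index.tolist(),
                          "values": self.nav_skill.tolist()},
            "motor_skill": {"index": self.motor_skill.index.tolist(),
                            "values": self.motor_skill.tolist()},
        }
        return json.dumps(payload, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            true_changepoints=tuple(d["true_changepoints"]),
            gender_offset=d["gender_offset"],
            country_table=pd.DataFrame(d["country_table"]),
            skill_link={g: tuple(v) for g, v in d["skill_link"].items()},
            nav_skill=pd.Series(d["nav_skill"]["values"],
                                index=d["nav_skill"]["index"], name="nav_skill"),
            motor_skill=pd.Series(d["motor_skill"]["values"],
                                  index=d["motor_skill"]["index"], name="motor_skill"),
        )


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a cohort table plus its ground truth. Deterministic per seed.

    Returns a DataFrame with one row per participant (columns:
    participant_id, age, gender, education, home_env, commute, country,
    sleep_hours) and the :class:`GroundTruth` used to produce it.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    lo, hi = config.age_range
    codes = config.country_codes
    clusters = config.resolved_clusters()
    weird = config.resolved_weird()
    shifts = dict(config.cluster_shifts or {})

    # country-level draws happen first, in a fixed order
    intercepts = rng.normal(0.0, config.country_intercept_sd, len(codes))
    abs_lat = rng.uniform(0.0, 60.0, len(codes))
    log_gdp = rng.normal(10.0, 0.5, len(codes))
    gdp = np.exp(log_gdp)
    effective = (
        intercepts
        + np.array([shifts.get(clusters[c], 0.0) for c in codes])
        + config.latitude_effect * (abs_lat - abs_lat.mean())
        + config.gdp_effect * (log_gdp - log_gdp.mean())
    )
    country_table = pd.DataFrame({
        "country": list(codes),
        "intercept": intercepts,
        "effective_intercept": effective,
        "cluster": [clusters[c] for c in codes],
        "weird": [weird[c] for c in codes],
        "abs_latitude": abs_lat,
        "gdp_per_capita": gdp,
    })

    ages_support = np.arange(lo, hi + 1)
    if config.age_weights is None:
        ages = rng.integers(lo, hi + 1, n)
    else:
        w = np.asarray(config.age_weights, dtype=float)
        ages = rng.choice(ages_support, size=n, p=w / w.sum())
    woman = rng.random(n) < 0.5
    tertiary = rng.random(n) < 0.72
    city = rng.random(n) < 0.30
    commute_idx = rng.choice(3, size=n, p=[0.40, 0.35, 0.25])
    country_idx = rng.integers(0, len(codes), n)

    latent = (
        piecewise_trend(ages, config)
        + np.where(woman, +0.5, -0.5) * config.gender_offset
        + effective[country_idx]
        + rng.normal(0.0, config.residual_sd, n)
    )
    if config.round_to_hours:
        sleep = np.clip(np.rint(latent), *config.sleep_support).astype(int)
    else:
        sleep = latent

    pid = np.array([f"p{i:07d}" for i in range(n)])
    records = pd.DataFrame({
        "participant_id": pid,
        "age": ages.astype(int),
        "gender": np.where(woman, "woman", "man"),
        "education": np.where(tertiary, "tertiary", "secondary"),
        "home_env": np.where(city, "city", "non-city"),
        "commute": np.asarray(COMMUTE)[commute_idx],
        "country": np.asarray(codes)[country_idx],
        "sleep_hours": sleep,
    })

    # latent skills: navigation skill carries the sleep link per age group
    link = config.resolved_skill_link()
    groups = assign_age_groups(ages, config.true_changepoints)
    s = np.asarray(sleep, dtype=float) - 7.0
    lin = np.array([link[g][0] for g in groups])
    quad = np.array([link[g][1] for g in groups])
    nav = (
        config.nav_skill_base
        + lin * s + quad * s * s
        + rng.normal(0.0, config.nav_skill_sd, n)
    )
    motor = config.motor_skill_base + rng.normal(0.0, config.motor_skill_sd, n)
    nav_skill = pd.Series(np.clip(nav, 0.02, 1.0), index=pid, name="nav_skill")
    motor_skill = pd.Series(np.clip(motor, 0.02, 1.0), index=pid, name="motor_skill")

    truth = GroundTruth(
        true_changepoints=tuple(float(c) for c in config.true_changepoints),
        gender_offset=config.gender_offset,
        country_table=country_table,
        skill_link=link,
        nav_skill=nav_skill,
        motor_skill=motor_skill,
        config=config,
    )
    return records, truth


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LevelSpec:
    level: int
    checkpoints: tuple[tuple[float, float], ...]
    tutorial: bool

    def __post_init__(self) -> None:
        if len(self.checkpoints) < 2:
            raise ConfigError(f"level {self.level} needs >= 2 checkpoints")

    @property
    def polyline(self) -> np.ndarray:
        return np.asarray(self.checkpoints, dtype=float)

    @property
    def ideal_length(self) -> float:
        p = self.polyline
        return float(np.hypot(*np.diff(p, axis=0).T).sum())


def default_level_specs() -> tuple[LevelSpec, ...]:
    """Two tutorial levels plus four wayfinding levels (ids 6, 7, 8, 11)."""
    return (
        LevelSpec(1, ((100.0, 100.0), (500.0, 400.0)), tutorial=True),
        LevelSpec(2, ((80.0, 420.0), (620.0, 140.0)), tutorial=True),
        LevelSpec(6, ((100.0, 100.0), (420.0, 160.0), (480.0, 470.0)), tutorial=False),
        LevelSpec(7, ((60.0, 300.0), (300.0, 80.0), (560.0, 220.0), (620.0, 520.0)),
                  tutorial=False),
        LevelSpec(8, ((500.0, 60.0), (140.0, 180.0), (220.0, 480.0), (600.0, 400.0)),
                  tutorial=False),
        LevelSpec(11, ((80.0, 80.0), (360.0, 120.0), (600.0, 300.0), (380.0, 520.0),
                       (120.0, 420.0)), tutorial=False),
    )


@dataclass(frozen=True)
class TrajectoryConfig:
    level_specs: tuple[LevelSpec, ...] = field(default_factory=default_level_specs)
    sample_period_ms: int = 500
    speed_px_s: float = 150.0
    detour_gain: float = 1.2
    motor_noise_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_period_ms <= 0:
            raise ConfigError("sample_period_ms must be > 0")
        if self.speed_px_s <= 0:
            raise ConfigError("speed_px_s must be > 0")
        n_tut = sum(1 for s in self.level_specs if s.tutorial)
        n_way = sum(1 for s in self.level_specs if not s.tutorial)
        if n_tut != 2 or n_way < 1:
            raise ConfigError("expected exactly 2 tutorial levels and >= 1 wayfinding level")
        if len({s.level for s in self.level_specs}) != len(self.level_specs):
            raise ConfigError("duplicate level ids in level_specs")

    @property
    def step_px(self) -> float:
        return self.speed_px_s * self.sample_period_ms / 1000.0


def _resample_polyline(verts: np.ndarray, step: float) -> np.ndarray:
    """Points along the polyline every ``step`` of arclength, keeping every
    vertex, so the sampled path length equals the polyline length exactly."""
    seg = np.hypot(*np.diff(verts, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total == 0:
        return verts[:1].copy()
    grid = np.arange(0.0, total, step)
    dist = np.unique(np.concatenate([grid, cum]))
    x = np.interp(dist, cum, verts[:, 0])
    y = np.interp(dist, cum, verts[:, 1])
    return np.column_stack([x, y])


def _one_path(spec: LevelSpec, nav: float, motor: float,
              tconfig: TrajectoryConfig, rng: np.random.Generator) -> np.ndarray:
    verts = spec.polyline
    if not spec.tutorial and nav < 1.0 and tconfig.detour_gain > 0:
        # skill-dependent detour waypoint in the middle of each leg
        out = [verts[0]]
        for a, b in zip(verts[:-1], verts[1:]):
            d = b - a
            leg = float(np.hypot(*d))
            normal = np.array([-d[1], d[0]]) / max(leg, 1e-9)
            amp = 0.5 * tconfig.detour_gain * (1.0 - nav) * leg
            amp *= rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
            out.append((a + b) / 2 + amp * normal)
            out.append(b)
        verts = np.asarray(out)
    pts = _resample_polyline(verts, tconfig.step_px)
    jitter_sd = tconfig.motor_noise_sd * (1.0 - motor)
    if jitter_sd > 0 and len(pts) > 2:
        pts = pts.copy()
        pts[1:-1] += rng.normal(0.0, jitter_sd, (len(pts) - 2, 2))
    return pts


def generate_trajectories(records: pd.DataFrame, tconfig: TrajectoryConfig,
                          truth: GroundTruth) -> list[Trajectory]:
    """One trajectory per participant x level. Deterministic per seed.

    Tutorial paths degrade only with (1 - motor skill); wayfinding paths
    additionally inflate with (1 - navigation skill), so expected wayfinding
    length is decreasing in navigation skill.
    """
    if len(records) == 0:
        return []
    missing = set(records["participant_id"]) - set(truth.nav_skill.index)
    if missing:
        raise ConfigError(f"{len(missing)} participants lack latent skills in truth")
    rng = np.random.default_rng(tconfig.seed)
    period = tconfig.sample_period_ms
    nav = truth.nav_skill
    motor = truth.motor_skill
    out: list[Trajectory] = []
    for pid in records["participant_id"]:
        pn, pm = float(nav[pid]), float(motor[pid])
        for spec in tconfig.level_specs:
            pts = _one_path(spec, pn, pm, tconfig, rng)
            t = np.arange(len(pts), dtype=np.int64) * period
            out.append(Trajectory(participant_id=pid, level=spec.level,
                                  tutorial=spec.tutorial, t_ms=t, xy=pts))
    return out
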