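"""Cohort analysis stages: inclusion filtering, age curves, effect sizes,
the sleep mixed model with country conditional modes, and the
sleep-by-performance quadratic models.

All stages operate on a cohort DataFrame with columns
``participant_id, age, gender, education, home_env, commute, country,
sleep_hours`` (the schema written by :mod:`sleepcourse.synthetic`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from ._exceptions import ConfigError, DataError, DegenerateDataError
from ._util import AGE_GROUP_LABELS, assign_age_groups
from .changepoint import Signal

__all__ = [
    "FilterConfig",
    "EffectSize",
    "ModelSummary",
    "PerformanceModelResult",
    "apply_inclusion_filters",
    "bin_age_curve",
    "per_age_mean_signal",
    "hedges_g",
    "sleeper_proportions",
    "fit_sleep_lmm",
    "conditional_mode_vs_raw",
    "fit_performance_model",
    "assign_age_groups",
]

_Z95 = scipy.stats.norm.ppf(0.975)


@dataclass(frozen=True)
class FilterConfig:
    """Inclusion rules: age ceiling, sleep range (inclusive), minimum
    per-country sample size (applied after the row filters)."""

    max_age: int = 70
    sleep_range: tuple[int, int] = (5, 10)
    min_country_n: int = 500

    def __post_init__(self) -> None:
        lo, hi = self.sleep_range
        if lo > hi:
            raise ConfigError("sleep_range must be ordered")
        if self.min_country_n < 1:
            raise ConfigError("min_country_n must be >= 1")


def apply_inclusion_filters(
    records: pd.DataFrame, config: FilterConfig = FilterConfig()
) -> tuple[pd.DataFrame, dict]:
    """Drop over-age rows, out-of-range sleep reports, then small countries.

    A row failing several rules is counted once, with priority
    age > sleep_high > sleep_low. Returns (kept records, report dict).
    """
    lo, hi = config.sleep_range
    age_bad = records["age"] > config.max_age
    high_bad = ~age_bad & (records["sleep_hours"] > hi)
    low_bad = ~age_bad & ~high_bad & (records["sleep_hours"] < lo)
    kept = records[~(age_bad | high_bad | low_bad)]

    counts = kept["country"].value_counts()
    small = counts[counts < config.min_country_n].index
    country_bad = kept["country"].isin(small)
    out = kept[~country_bad].reset_index(drop=True)
    report = {
        "n_input": int(len(records)),
        "n_kept": int(len(out)),
        "age": int(age_bad.sum()),
        "sleep_high": int(high_bad.sum()),
        "sleep_low": int(low_bad.sum()),
        "country_small": int(country_bad.sum()),
        "countries_removed": sorted(small.tolist()),
        "n_countries_kept": int(out["country"].nunique()),
    }
    return out, report


def bin_age_curve(
    records: pd.DataFrame,
    window: int = 3,
    group_by: str | None = None,
) -> pd.DataFrame:
    """Mean sleep within non-overlapping age windows of ``window`` years.

    Windows start at the youngest observed age ([19-21], [22-24], ... by
    default). Returns columns ``bin_center, mean_sleep, ci_half_width,
    n`` (plus the ``group_by`` column when stratified); the 95% CI
    half-width is 1.96 x SE.
    """
    if records.empty:
        raise DataError("no records to bin")
    start = int(records["age"].min())
    idx = (records["age"] - start) // window
    centers = start + idx * window + (window - 1) / 2.0
    df = records.assign(_bin=centers)
    keys = ["_bin"] if group_by is None else [group_by, "_bin"]
    grouped = df.groupby(keys, observed=True)["sleep_hours"]
    out = grouped.agg(mean_sleep="mean", sd=lambda s: s.std(ddof=1), n="size")
    out = out.reset_index().rename(columns={"_bin": "bin_center"})
    with np.errstate(invalid="ignore"):
        out["ci_half_width"] = _Z95 * out["sd"] / np.sqrt(out["n"])
    return out.drop(columns="sd")


def per_age_mean_signal(records: pd.DataFrame) -> Signal:
    """One mean sleep value per integer age; errors on gaps in coverage."""
    if records.empty:
        raise DataError("no records")
    means = records.groupby("age")["sleep_hours"].mean().sort_index()
    ages = means.index.to_numpy()
    expected = np.arange(ages.min(), ages.max() + 1)
    missing = sorted(set(expected) - set(ages))
    if missing:
        raise DataError(f"no participants at ages {missing}")
    return Signal(positions=ages.astype(float), values=means.to_numpy())


@dataclass(frozen=True)
class EffectSize:
    """Hedge's g with a normal-approximation 95% CI."""

    g: float
    ci_low: float
    ci_high: float
    n1: int
    n2: int


def _summary(group) -> tuple[float, float, int]:
    if isinstance(group, (tuple, list)) and len(group) == 3:
        m, sd, n = group
        return float(m), float(sd), int(n)
    x = np.asarray(group, dtype=float)
    if x.size < 2:
        raise DataError("each group needs n >= 2 (or a (mean, sd, n) triple)")
    return float(x.mean()), float(x.std(ddof=1)), int(x.size)


def hedges_g(group_a, group_b) -> EffectSize:
    """Pooled-SD standardized mean difference with small-sample correction.

    ``g = J * (m_a - m_b) / s_pooled`` with the (n-1)-weighted pooled SD
    and ``J = 1 - 3 / (4(n1 + n2) - 9)``; the 95% CI uses
    ``SE^2 = (n1 + n2)/(n1 n2) + g^2 / (2(n1 + n2))``. Each argument is
    raw values or a ``(mean, sd, n)`` triple.
    """
    m1, s1, n1 = _summary(group_a)
    m2, s2, n2 = _summary(group_b)
    if n1 < 2 or n2 < 2:
        raise DataError("need n >= 2 in both groups")
    if s1 < 0 or s2 < 0:
        raise DataError("negative SD")
    pooled = np.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2))
    if pooled == 0:
        raise DegenerateDataError("pooled SD is zero: effect size undefined")
    j = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    g = j * (m1 - m2) / pooled
    se = np.sqrt((n1 + n2) / (n1 * n2) + g ** 2 / (2.0 * (n1 + n2)))
    return EffectSize(g=float(g), ci_low=float(g - _Z95 * se),
                      ci_high=float(g + _Z95 * se), n1=n1, n2=n2)


def sleeper_proportions(
    records: pd.DataFrame,
    changepoints: Sequence[float] = (33.0, 53.0),
    short_hours: Sequence[int] = (5,),
    long_hours: Sequence[int] = (9, 10),
) -> pd.DataFrame:
    """Short (5 h) and long (9-10 h) sleeper shares per gender x age group."""
    df = records.assign(agegroup=assign_age_groups(records["age"], changepoints))
    cells = []
    for (gender, group), sub in df.groupby(["gender", "agegroup"], observed=False):
        n = len(sub)
        if n == 0:
            cells.append((gender, group, np.nan, np.nan, 0, True))
            continue
        short = sub["sleep_hours"].isin(short_hours).mean()
        long_ = sub["sleep_hours"].isin(long_hours).mean()
        cells.append((gender, group, short, long_, n, False))
    return pd.DataFrame(
        cells, columns=["gender", "agegroup", "prop_short", "prop_long", "n", "empty"]
    )


@dataclass
class ModelSummary:
    """Fixed effects, per-country conditional modes and variance components
    of the sleep mixed model."""

    params: pd.Series
    conf_int: pd.DataFrame
    conditional_modes: pd.Series
    random_intercept_var: float
    residual_var: float
    converged: bool
    formula: str


_LMM_FORMULA = (
    "sleep_hours ~ age_c * (C(gender, Treatment('man')) "
    "+ C(education, Treatment('secondary')) "
    "+ C(home_env, Treatment('non-city')) "
    "+ C(commute, Treatment('<30min'))) + age_c2"
)


def fit_sleep_lmm(records: pd.DataFrame) -> ModelSummary:
    """Maximum-likelihood mixed model of sleep on demographics with a
    random intercept per country.

    Age is mean-centered before forming its square. Conditional modes are
    the predicted random intercepts (BLUPs): a country's deviation, in
    hours, from the population-level prediction.
    """
    if records["country"].nunique() < 2:
        raise DataError("need >= 2 countries for a random intercept")
    for col in ("gender", "education", "home_env", "commute"):
        if records[col].nunique() < 2:
            raise DataError(f"factor {col!r} has a single level: singular design")
    df = records.copy()
    age_c = df["age"] - df["age"].mean()
    df["age_c"] = age_c
    df["age_c2"] = age_c ** 2
    model = smf.mixedlm(_LMM_FORMULA, data=df, groups=df["country"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # bfgs stalls when the group variance sits on the zero boundary;
        # lbfgs handles that case, so try both before giving up
        result = model.fit(reml=False)
        if not result.converged:
            result = model.fit(reml=False, method="lbfgs")
    try:
        modes = pd.Series(
            {g: float(re.iloc[0]) for g, re in result.random_effects.items()},
            name="conditional_mode",
        ).sort_index()
    except ValueError:
        # group variance estimated at exactly zero: every BLUP is zero
        modes = pd.Series(0.0, index=sorted(records["country"].unique()),
                          name="conditional_mode")
    return ModelSummary(
        params=result.fe_params,
        conf_int=result.conf_int().loc[result.fe_params.index],
        conditional_modes=modes,
        random_intercept_var=float(result.cov_re.iloc[0, 0]),
        residual_var=float(result.scale),
        converged=bool(result.converged),
        formula=_LMM_FORMULA,
    )


def conditional_mode_vs_raw(
    records: pd.DataFrame, modes: Mapping[str, float] | pd.Series
) -> tuple[float, float]:
    """Pearson correlation between per-country raw mean sleep and the
    country conditional modes. Returns (r, p)."""
    modes = pd.Series(modes)
    raw = records.groupby("country")["sleep_hours"].mean()
    common = raw.index.intersection(modes.index)
    if len(common) < 3:
        raise DataError("need >= 3 countries")
    x, y = raw[common].to_numpy(), modes[common].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant vector: correlation undefined")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class PerformanceModelResult:
    """OLS fit of performance on age-group-specific sleep quadratics."""

    outcome: str
    params: pd.Series
    conf_int: pd.DataFrame
    group_curves: pd.DataFrame  # agegroup, b1, b2, b2_ci_low/high, peak_sleep, peak CI
    nobs: int


_SLEEP_CENTER = 7.0


def fit_performance_model(
    scores: pd.DataFrame,
    records: pd.DataFrame,
    changepoints: Sequence[float] = (33.0, 53.0),
    outcomes: Sequence[str] = ("tp", "wf"),
) -> dict[str, PerformanceModelResult]:
    """Least-squares fit of ``performance ~ agegroup * (sleep + sleep^2)
    + education + home_env + commute`` for each outcome.

    Sleep enters centered at 7 h, so the fitted group-specific quadratic
    peak is ``7 - b1 / (2 b2)`` on the original scale; its CI uses the
    delta method.
    """
    df = scores.merge(records, on="participant_id", how="inner")
    if df.empty:
        raise DataError("no overlap between scores and records")
    df["agegroup"] = assign_age_groups(df["age"], changepoints)
    s = df["sleep_hours"].astype(float) - _SLEEP_CENTER
    df["s"] = s
    df["s2"] = s ** 2
    for g, sub in df.groupby("agegroup", observed=False):
        if sub["sleep_hours"].nunique() < 3:
            raise DataError(f"age group {g!r} has < 3 distinct sleep values")

    out: dict[str, PerformanceModelResult] = {}
    formula_rhs = (
        "C(agegroup, Treatment('young')) * (s + s2) "
        "+ C(education, Treatment('secondary')) "
        "+ C(home_env, Treatment('non-city')) "
        "+ C(commute, Treatment('<30min'))"
    )
    for outcome in outcomes:
        result = smf.ols(f"{outcome} ~ {formula_rhs}", data=df).fit()
        params, cov = result.params, result.cov_params()
        rows = []
        for group in AGE_GROUP_LABELS:
            lin_names = ["s"]
            quad_names = ["s2"]
            if group != "young":
                lin_names.append(f"C(agegroup, Treatment('young'))[T.{group}]:s")
                quad_names.append(f"C(agegroup, Treatment('young'))[T.{group}]:s2")
            l1 = pd.Series(0.0, index=params.index)
            l2 = pd.Series(0.0, index=params.index)
            l1[lin_names] = 1.0
            l2[quad_names] = 1.0
            b1 = float(params @ l1)
            b2 = float(params @ l2)
            b2_se = float(np.sqrt(l2 @ cov @ l2))
            if b2 != 0:
                peak = _SLEEP_CENTER - b1 / (2.0 * b2)
                grad = -l1 / (2.0 * b2) + l2 * b1 / (2.0 * b2 ** 2)
                peak_se = float(np.sqrt(grad @ cov @ grad))
            else:
                peak, peak_se = np.nan, np.nan
            rows.append({
                "agegroup": group,
                "b1": b1,
                "b2": b2,
                "b2_ci_low": b2 - _Z95 * b2_se,
                "b2_ci_high": b2 + _Z95 * b2_se,
                "peak_sleep": peak,
                "peak_ci_low": peak - _Z95 * peak_se,
                "peak_ci_high": peak + _Z95 * peak_se,
            })
        out[outcome] = PerformanceModelResult(
            outcome=outcome,
            params=params,
            conf_int=result.conf_int(),
            group_curves=pd.DataFrame(rows),
            nobs=int(result.nobs),
        )
    return out
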