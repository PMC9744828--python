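"""Supra-national clustering tests and country-level regressions.

* fixed-effects ANOVA F for a cluster factor on top of age and gender,
* a country-label permutation null for that F,
* latitude and GDP regressions of country-level sleep summaries,
* per-subgroup change-point detection (e.g. WEIRD vs non-WEIRD, gender).

The package ships two cluster taxonomies (a 7-cluster historical-economic
grouping and an 11-cluster cultural grouping) as a plain-text table;
``England`` denotes the United Kingdom in that table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from ._exceptions import ConfigError, DataError, DegenerateDataError
from .changepoint import optimal_segmentation
from .pipeline import per_age_mean_signal

__all__ = [
    "PermutationOutcome",
    "cluster_anova_f",
    "permutation_null",
    "latitude_correlation",
    "gdp_latitude_regression",
    "subgroup_changepoints",
    "load_packaged_clusters",
]


def load_packaged_clusters() -> pd.DataFrame:
    """The packaged country table: country, maddison_cluster (7 labels),
    cultural_cluster (11 labels), weird flag.

    The weird column is a heuristic default (historical-economic Western
    Europe + Western Offshoot clusters); override it with study-specific
    labels where available.
    """
    ref = resources.files("sleepcourse").joinpath("data/country_clusters.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def _design(records: pd.DataFrame, cluster_map: Mapping[str, str]):
    """Response vector plus reduced (intercept, age, gender) and cluster
    dummy blocks of the ANOVA design."""
    unmapped = sorted(set(records["country"]) - set(cluster_map))
    if unmapped:
        raise ConfigError(f"countries without a cluster: {unmapped}")
    clusters = records["country"].map(dict(cluster_map))
    labels = sorted(clusters.unique())
    if len(labels) < 2:
        raise ConfigError("need >= 2 clusters")
    n = len(records)
    y = records["sleep_hours"].to_numpy(dtype=float)
    x0 = np.column_stack([
        np.ones(n),
        records["age"].to_numpy(dtype=float),
        (records["gender"] == "woman").to_numpy(dtype=float),
    ])
    # k-1 treatment dummies; reference = first label
    codes = clusters.map({lab: i for i, lab in enumerate(labels)}).to_numpy()
    dummies = (codes[:, None] == np.arange(1, len(labels))[None, :]).astype(float)
    return y, x0, dummies


def _rss(y: np.ndarray, x: np.ndarray) -> float:
    _, res, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if res.size:
        return float(res[0])
    fit = x @ np.linalg.lstsq(x, y, rcond=None)[0]
    return float(((y - fit) ** 2).sum())


def _partial_f(y, x0, dummies) -> tuple[float, int, int]:
    x_full = np.column_stack([x0, dummies])
    rss_full = _rss(y, x_full)
    rss_red = _rss(y, x0)
    df1 = dummies.shape[1]
    df2 = len(y) - x_full.shape[1]
    if df2 <= 0 or rss_full <= 0:
        raise DataError("not enough residual degrees of freedom")
    f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    return float(f), df1, df2


def cluster_anova_f(
    records: pd.DataFrame, cluster_map: Mapping[str, str]
) -> tuple[float, int, int]:
    """F statistic of the cluster factor in a fixed-effects model of sleep
    on age (linear), gender and cluster. Returns (F, df1, df2) with
    df1 = k - 1 and df2 = n - p."""
    return _partial_f(*_design(records, cluster_map))


@dataclass(frozen=True)
class PermutationOutcome:
    """Observed cluster F against a country-label shuffle null."""

    observed_f: float
    null_f: np.ndarray
    n_shuffles: int
    seed: int
    df1: int
    df2: int

    @property
    def p_value(self) -> float:
        """Share of null F values >= observed, with the add-one convention
        (so p is never exactly 0: p in [1/(n+1), 1])."""
        return float(
            (1 + int(np.sum(self.null_f >= self.observed_f)))
            / (self.n_shuffles + 1)
        )


def permutation_null(
    records: pd.DataFrame,
    cluster_map: Mapping[str, str],
    n_shuffles: int = 100,
    seed: int = 0,
    shuffle_unit: str = "participant",
) -> PermutationOutcome:
    """Shuffle country labels and recompute the cluster F each time.

    ``shuffle_unit="participant"`` (default) permutes the country-label
    vector across participants before mapping to clusters; the null F is
    then a central F draw (mean near 1, spread ``sqrt(2/df1)``).
    ``shuffle_unit="country"`` instead permutes the country -> cluster
    assignment across the country labels, preserving within-country
    structure; with real between-country differences this null is far
    from 1 but remains exchangeable with the observed F when no cluster
    structure exists. Deterministic under a fixed seed.
    """
    if n_shuffles < 1:
        raise DataError("n_shuffles must be >= 1")
    if shuffle_unit not in ("participant", "country"):
        raise ConfigError("shuffle_unit must be 'participant' or 'country'")
    cluster_map = dict(cluster_map)
    y, x0, dummies = _design(records, cluster_map)
    observed, df1, df2 = _partial_f(y, x0, dummies)

    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    if shuffle_unit == "participant":
        # permuting cluster codes across rows == shuffling each
        # participant's country label, then mapping to clusters
        codes = np.argmax(np.column_stack(
            [1 - dummies.sum(axis=1), dummies]), axis=1)
        k = dummies.shape[1] + 1
        for i in range(n_shuffles):
            perm_codes = rng.permutation(codes)
            dummies_i = (perm_codes[:, None] == np.arange(1, k)[None, :]).astype(float)
            null[i], _, _ = _partial_f(y, x0, dummies_i)
    else:
        countries = sorted(cluster_map)
        values = [cluster_map[c] for c in countries]
        for i in range(n_shuffles):
            perm = rng.permutation(len(countries))
            shuffled = {c: values[j] for c, j in zip(countries, perm)}
            _, _, dummies_i = _design(records, shuffled)
            null[i], _, _ = _partial_f(y, x0, dummies_i)
    return PermutationOutcome(observed_f=observed, null_f=null,
                              n_shuffles=n_shuffles, seed=seed, df1=df1, df2=df2)


def latitude_correlation(summaries: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between country mean sleep and absolute
    latitude. Expects columns ``mean_sleep`` and ``abs_latitude``."""
    df = summaries.dropna(subset=["mean_sleep", "abs_latitude"])
    if len(df) < 3:
        raise DataError("need >= 3 countries with latitude")
    x = df["abs_latitude"].to_numpy(dtype=float)
    y = df["mean_sleep"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant input: correlation undefined")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def gdp_latitude_regression(
    summaries: pd.DataFrame,
    response: str = "mean_sleep",
    include_weird: bool = False,
    log_gdp: bool = False,
) -> pd.DataFrame:
    """Country-level OLS of ``response`` on GDP per capita and absolute
    latitude (optionally plus the WEIRD flag).

    Returns a table with coef, se, t, p and df_resid per predictor.
    """
    cols = ["gdp_per_capita", "abs_latitude"] + (["weird"] if include_weird else [])
    df = summaries.dropna(subset=[response, *cols]).copy()
    if len(df) <= len(cols) + 1:
        raise DataError("too few countries for the requested regression")
    x = df[cols].astype(float)
    if log_gdp:
        x["gdp_per_capita"] = np.log(x["gdp_per_capita"])
    x = sm.add_constant(x)
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        raise DataError("collinear predictors")
    res = sm.OLS(df[response].astype(float), x).fit()
    out = pd.DataFrame({
        "coef": res.params,
        "se": res.bse,
        "t": res.tvalues,
        "p": res.pvalues,
    })
    out["df_resid"] = int(res.df_resid)
    return out


def subgroup_changepoints(
    records: pd.DataFrame,
    split: str,
    beta: float = 0.02,
) -> dict[str, tuple[float, ...]]:
    """Per-subgroup change points: per-age mean signal then optimal
    segmentation at the given penalty, for each level of ``split``
    (e.g. ``"gender"`` or a WEIRD flag column)."""
    if split not in records.columns:
        raise ConfigError(f"no column {split!r} in records")
    out: dict[str, tuple[float, ...]] = {}
    for level, sub in records.groupby(split, observed=True):
        signal = per_age_mean_signal(sub)
        out[str(level)] = optimal_segmentation(signal, beta).changepoints
    return out
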