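import numpy as np
import pandas as pd
import pytest

from sleepcourse import ConfigError, DataError, DegenerateDataError
from sleepcourse.geo import (
    cluster_anova_f,
    gdp_latitude_regression,
    latitude_correlation,
    load_packaged_clusters,
    permutation_null,
    subgroup_changepoints,
)
from sleepcourse.synthetic import CohortConfig, generate_cohort


def cluster_map_of(truth):
    return dict(zip(truth.country_table["country"], truth.country_table["cluster"]))


def toy_anova_table():
    """30 rows, 3 countries in 2 clusters, deterministic values."""
    rng = np.random.default_rng(42)
    countries = np.repeat(["K01", "K02", "K03"], 10)
    return pd.DataFrame({
        "participant_id": [f"p{i}" for i in range(30)],
        "age": rng.integers(19, 71, 30),
        "gender": rng.choice(["man", "woman"], 30),
        "country": countries,
        "sleep_hours": rng.integers(5, 11, 30),
    }), {"K01": "A", "K02": "B", "K03": "A"}


class TestClusterAnova:
    def test_matches_sums_of_squares_oracle(self):
        records, cmap = toy_anova_table()
        f, df1, df2 = cluster_anova_f(records, cmap)
        # independent oracle: explicit projection algebra via pseudo-inverse
        y = records["sleep_hours"].to_numpy(float)
        x0 = np.column_stack([np.ones(30), records["age"],
                              (records["gender"] == "woman").astype(float)])
        d = (records["country"].map(cmap) == "B").to_numpy(float)[:, None]
        xf = np.column_stack([x0, d])

        def rss(x):
            beta = np.linalg.pinv(x) @ y
            return float(((y - x @ beta) ** 2).sum())

        f_oracle = ((rss(x0) - rss(xf)) / 1) / (rss(xf) / (30 - xf.shape[1]))
        assert f == pytest.approx(f_oracle, abs=1e-8)
        assert (df1, df2) == (1, 26)

    def test_unmapped_country_rejected(self):
        records, cmap = toy_anova_table()
        del cmap["K03"]
        with pytest.raises(ConfigError, match="without a cluster"):
            cluster_anova_f(records, cmap)

    def test_single_cluster_rejected(self):
        records, _ = toy_anova_table()
        with pytest.raises(ConfigError):
            cluster_anova_f(records, {"K01": "A", "K02": "A", "K03": "A"})

    def test_invariant_to_cluster_relabeling(self):
        records, cmap = toy_anova_table()
        f1, *_ = cluster_anova_f(records, cmap)
        renamed = {k: {"A": "zebra", "B": "aardvark"}[v] for k, v in cmap.items()}
        f2, *_ = cluster_anova_f(records, renamed)
        assert f1 == pytest.approx(f2, abs=1e-10)

    def test_signal_detected(self):
        cfg = CohortConfig(n_participants=20_000, n_countries=8,
                           cluster_labels=("A", "B"), cluster_shifts={"B": 0.3},
                           country_intercept_sd=0.0, seed=1)
        records, truth = generate_cohort(cfg)
        f, df1, df2 = cluster_anova_f(records, cluster_map_of(truth))
        # F under H0 would be ~1; a 0.3 h shift at n=20k is enormous
        assert f > 100


class TestPermutationNull:
    def test_determinism(self):
        records, cmap = toy_anova_table()
        a = permutation_null(records, cmap, n_shuffles=20, seed=9)
        b = permutation_null(records, cmap, n_shuffles=20, seed=9)
        np.testing.assert_array_equal(a.null_f, b.null_f)

    def test_invalid_shuffle_count(self):
        records, cmap = toy_anova_table()
        with pytest.raises(DataError):
            permutation_null(records, cmap, n_shuffles=0)

    def test_p_value_bounds(self):
        records, cmap = toy_anova_table()
        out = permutation_null(records, cmap, n_shuffles=50, seed=2)
        assert 1 / 51 <= out.p_value <= 1.0
        assert out.null_f.size == 50

    def test_null_f_mean_near_one_participant_shuffle(self):
        cfg = CohortConfig(n_participants=20_000, n_countries=12,
                           cluster_labels=("A", "B", "C", "D"), seed=3)
        records, truth = generate_cohort(cfg)
        out = permutation_null(records, cluster_map_of(truth),
                               n_shuffles=100, seed=3)
        # E[F] = df2/(df2 - 2) ~ 1; SE of the mean of 100 draws ~ 0.08
        assert out.null_f.mean() == pytest.approx(1.0, abs=0.25)

    def test_country_shuffle_calibrated_with_country_noise(self):
        # with iid country intercepts and no cluster shift the observed F
        # is exchangeable with country-level shuffles
        hits = 0
        for i in range(40):
            cfg = CohortConfig(n_participants=1_500, n_countries=12,
                               cluster_labels=("A", "B", "C"), seed=500 + i)
            records, truth = generate_cohort(cfg)
            out = permutation_null(records, cluster_map_of(truth),
                                   n_shuffles=60, seed=i,
                                   shuffle_unit="country")
            hits += out.p_value > 0.05
        assert hits / 40 >= 0.80  # expect ~0.95

    def test_strong_shift_beats_every_shuffle(self):
        cfg = CohortConfig(n_participants=20_000, n_countries=12,
                           cluster_labels=("A", "B", "C", "D"),
                           cluster_shifts={"B": 0.3, "D": 0.3}, seed=4)
        records, truth = generate_cohort(cfg)
        out = permutation_null(records, cluster_map_of(truth),
                               n_shuffles=100, seed=4)
        assert out.observed_f > out.null_f.max()
        assert out.p_value == pytest.approx(1 / 101)

    def test_bad_unit_rejected(self):
        records, cmap = toy_anova_table()
        with pytest.raises(ConfigError):
            permutation_null(records, cmap, n_shuffles=5, shuffle_unit="city")


class TestLatitude:
    def summaries(self, slope=0.01, noise=0.0, n=40, seed=0):
        rng = np.random.default_rng(seed)
        lat = rng.uniform(0, 60, n)
        return pd.DataFrame({
            "country": [f"K{i:02d}" for i in range(n)],
            "mean_sleep": 6.8 + slope * lat + rng.normal(0, noise, n),
            "abs_latitude": lat,
            "gdp_per_capita": np.exp(rng.normal(10, 0.5, n)),
            "weird": rng.random(n) < 0.3,
        })

    def test_exact_linear_gives_r_one(self):
        r, p = latitude_correlation(self.summaries(noise=0.0))
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_shuffled_latitude_r_near_zero(self):
        df = self.summaries(noise=0.0)
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(30):
            shuffled = df.assign(abs_latitude=rng.permutation(df["abs_latitude"]))
            rs.append(latitude_correlation(shuffled)[0])
        assert abs(np.mean(rs)) < 0.1

    def test_sign_flip(self):
        pos, _ = latitude_correlation(self.summaries(slope=0.01, noise=0.05))
        neg, _ = latitude_correlation(self.summaries(slope=-0.01, noise=0.05))
        assert pos > 0 > neg

    def test_constant_rejected(self):
        df = self.summaries().assign(mean_sleep=7.0)
        with pytest.raises(DegenerateDataError):
            latitude_correlation(df)


class TestGdpLatitudeRegression:
    def test_matches_normal_equations_oracle(self):
        df = pd.DataFrame({
            "country": list("abcde"),
            "mean_sleep": [6.5, 7.0, 7.2, 6.8, 7.4],
            "gdp_per_capita": [1e4, 2e4, 3e4, 1.5e4, 4e4],
            "abs_latitude": [10.0, 30.0, 50.0, 20.0, 55.0],
        })
        table = gdp_latitude_regression(df)
        x = np.column_stack([np.ones(5), df["gdp_per_capita"], df["abs_latitude"]])
        y = df["mean_sleep"].to_numpy()
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(
            table["coef"].to_numpy(), beta, atol=1e-8)
        assert table["df_resid"].iloc[0] == 2

    def test_latitude_effect_recovered_gdp_null(self):
        cfg = CohortConfig(n_participants=60_000, n_countries=40,
                           latitude_effect=0.01, seed=12)
        records, truth = generate_cohort(cfg)
        summaries = (records.groupby("country")["sleep_hours"].mean()
                     .rename("mean_sleep").reset_index()
                     .merge(truth.country_table, on="country"))
        table = gdp_latitude_regression(summaries)
        lat = table.loc["abs_latitude"]
        gdp = table.loc["gdp_per_capita"]
        assert lat["p"] < 0.01
        assert gdp["p"] > 0.05

    def test_weird_flag_is_nuisance_robust(self):
        cfg = CohortConfig(n_participants=60_000, n_countries=40,
                           latitude_effect=0.01, seed=12)
        records, truth = generate_cohort(cfg)
        summaries = (records.groupby("country")["sleep_hours"].mean()
                     .rename("mean_sleep").reset_index()
                     .merge(truth.country_table, on="country"))
        without = gdp_latitude_regression(summaries)
        with_weird = gdp_latitude_regression(summaries, include_weird=True)
        assert with_weird.loc["abs_latitude", "p"] < 0.01
        assert np.sign(with_weird.loc["abs_latitude", "coef"]) == \
            np.sign(without.loc["abs_latitude", "coef"])

    def test_too_few_countries_rejected(self):
        df = pd.DataFrame({"country": ["a", "b"], "mean_sleep": [7, 7.2],
                           "gdp_per_capita": [1e4, 2e4],
                           "abs_latitude": [10.0, 20.0]})
        with pytest.raises(DataError):
            gdp_latitude_regression(df)


def assert_cps_close(cps, truth, tol=1.0):
    """Change points match ground truth within tol years (a kink at age c
    is legitimately reported at c or c+1: the noise-free split is a tie)."""
    assert len(cps) == len(truth)
    for got, want in zip(cps, truth):
        assert abs(got - want) <= tol, f"{cps} vs {truth}"


class TestSubgroupChangepoints:
    def low_noise_cfg(self, **kw):
        return CohortConfig(n_participants=60_000, residual_sd=0.15,
                            country_intercept_sd=0.0, round_to_hours=False, **kw)

    def test_whole_cohort_subgroup_equals_global(self):
        from sleepcourse.changepoint import optimal_segmentation
        from sleepcourse.pipeline import per_age_mean_signal
        records, _ = generate_cohort(self.low_noise_cfg(seed=14))
        records = records.assign(all="everyone")
        sub = subgroup_changepoints(records, "all")
        global_cps = optimal_segmentation(per_age_mean_signal(records), 0.02).changepoints
        assert sub == {"everyone": global_cps}

    def test_identical_trends_same_changepoints(self):
        records, _ = generate_cohort(self.low_noise_cfg(seed=15))
        out = subgroup_changepoints(records, "gender")
        assert_cps_close(out["man"], (33.0, 53.0))
        assert_cps_close(out["woman"], (33.0, 53.0))
        # the two subgroup estimates agree up to the kink-boundary tie
        assert all(abs(a - b) <= 1 for a, b in zip(out["man"], out["woman"]))

    def test_offset_subgroup_detected(self):
        rec_a, _ = generate_cohort(self.low_noise_cfg(seed=16))
        rec_b, _ = generate_cohort(
            self.low_noise_cfg(seed=17, true_changepoints=(31.0, 51.0)))
        rec_a = rec_a.assign(weird=True)
        rec_b = rec_b.assign(weird=False,
                             participant_id="b" + rec_b["participant_id"])
        both = pd.concat([rec_a, rec_b], ignore_index=True)
        out = subgroup_changepoints(both, "weird")
        assert_cps_close(out["True"], (33.0, 53.0))
        assert_cps_close(out["False"], (31.0, 51.0))

    def test_unknown_column_rejected(self):
        records, _ = generate_cohort(CohortConfig(n_participants=100, seed=0))
        with pytest.raises(ConfigError):
            subgroup_changepoints(records, "hemisphere")


class TestPackagedClusters:
    def test_table_loads(self):
        table = load_packaged_clusters()
        assert table["maddison_cluster"].nunique() == 7
        assert table["cultural_cluster"].nunique() == 11
        assert table["country"].is_unique

    def test_every_country_clustered(self):
        table = load_packaged_clusters()
        assert table.notna().all().all()
        assert table["weird"].dtype == bool
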