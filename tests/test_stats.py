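"""Cohort statistics: normality, MANCOVA, post-hoc tests, correlations,
repeatability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mpfmap.stats import (
    cohort_stats,
    mancova,
    pearson_and_partial,
    repeatability,
    shapiro_wilk,
    tukey_hsd,
)
from mpfmap.synthetic import generate_cohort


def _null_cohort(seed, n=(23, 10, 21)):
    rng = np.random.default_rng(seed)
    total = sum(n)
    return pd.DataFrame({
        "group": (["control"] * n[0] + ["sz_positive"] * n[1]
                  + ["sz_negative"] * n[2]),
        "age": rng.normal(38.0, 9.0, total),
        "gm_mpf": rng.normal(6.44, 0.24, total),
        "pvwgm_mpf": rng.normal(9.22, 0.40, total),
        "wm_mpf": rng.normal(13.04, 0.56, total),
    })


class TestShapiroWilk:
    def test_reference_sample(self):
        # frozen reference from R's shapiro.test on the same vector
        x = [148, 154, 158, 160, 161, 162, 166, 170, 182, 195, 236]
        w, p = shapiro_wilk(x)
        assert w == pytest.approx(0.78881, abs=1e-3)
        assert p == pytest.approx(0.006704, abs=1e-3)

    def test_null_p_uniform_over_seeds(self):
        pvals = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            _, p = shapiro_wilk(rng.normal(size=200))
            pvals.append(p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([2.0, 2.0, 2.0, 2.0])

    def test_n_out_of_range(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestMancova:
    def test_matches_statsmodels_manova(self):
        statsmodels_mv = pytest.importorskip("statsmodels.multivariate.manova")
        coh = generate_cohort(seed=1)
        res = mancova(coh)
        mv = statsmodels_mv.MANOVA.from_formula(
            "gm_mpf + pvwgm_mpf + wm_mpf ~ C(group) + age", data=coh)
        tbl = mv.mv_test()
        ref_group = tbl.results["C(group)"]["stat"].loc["Wilks' lambda"]
        ref_age = tbl.results["age"]["stat"].loc["Wilks' lambda"]
        assert res["group"]["wilks_lambda"] == pytest.approx(
            float(ref_group["Value"]), rel=1e-8)
        assert res["group"]["F"] == pytest.approx(
            float(ref_group["F Value"]), rel=1e-8)
        assert res["age"]["wilks_lambda"] == pytest.approx(
            float(ref_age["Value"]), rel=1e-8)

    def test_rao_f_dfs_for_study_design(self):
        # 54 subjects, 3 responses: 2-level factor gives F(3, 49),
        # 3-level factor gives F(6, 96)
        coh = generate_cohort(seed=3)
        res3 = mancova(coh)
        assert (res3["group"]["df1"], round(res3["group"]["df2"])) == (6, 96)
        two = coh.copy()
        two["group"] = np.where(two["group"] == "control", "control", "sz")
        res2 = mancova(two)
        assert (res2["group"]["df1"], round(res2["group"]["df2"])) == (3, 49)

    def test_single_response_reduces_to_ancova_f(self):
        coh = generate_cohort(seed=2)
        res = mancova(coh, responses=("wm_mpf",))
        # extra-sum-of-squares F test of the group term in OLS with age
        y = coh["wm_mpf"].to_numpy()
        x_age = np.column_stack([np.ones(len(coh)), coh["age"]])
        dummies = pd.get_dummies(coh["group"], drop_first=True).to_numpy(float)
        x_full = np.column_stack([x_age, dummies])

        def rss(x):
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            r = y - x @ beta
            return r @ r

        rss_full, rss_red = rss(x_full), rss(x_age)
        df_num = dummies.shape[1]
        df_den = len(coh) - x_full.shape[1]
        f_ref = (rss_red - rss_full) / df_num / (rss_full / df_den)
        assert res["group"]["F"] == pytest.approx(f_ref, rel=1e-10)

    def test_null_wilks_near_one_large_n(self):
        coh = _null_cohort(seed=0, n=(2000, 2000, 2000))
        res = mancova(coh)
        assert res["group"]["wilks_lambda"] > 0.99

    def test_small_fixture_matches_brute_force_sscp(self):
        # n = 12, 2 groups: lambda from explicit SSCP matrix algebra
        df = pd.DataFrame({
            "group": ["a"] * 6 + ["b"] * 6,
            "age": [30, 35, 40, 45, 50, 55, 32, 37, 42, 47, 52, 57],
            "gm_mpf": [6.5, 6.4, 6.3, 6.6, 6.2, 6.5, 6.1, 6.0, 6.2, 5.9, 6.1, 6.0],
            "pvwgm_mpf": [9.3, 9.1, 9.2, 9.4, 9.0, 9.2, 8.9, 8.8, 9.0, 8.7, 8.9, 8.8],
            "wm_mpf": [13.1, 13.0, 12.9, 13.2, 12.8, 13.0, 12.6, 12.5, 12.7,
                       12.4, 12.6, 12.5],
        })
        res = mancova(df)
        y = df[["gm_mpf", "pvwgm_mpf", "wm_mpf"]].to_numpy()
        g = (df["group"] == "b").astype(float).to_numpy()[:, None]
        x_full = np.column_stack([np.ones(12), df["age"], g])
        x_red = np.column_stack([np.ones(12), df["age"]])

        def sscp(x):
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            r = y - x @ beta
            return r.T @ r

        e = sscp(x_full)
        h = sscp(x_red) - e
        lam = np.linalg.det(e) / np.linalg.det(e + h)
        assert res["group"]["wilks_lambda"] == pytest.approx(lam, rel=1e-10)

    def test_too_small_groups_rejected(self):
        df = _null_cohort(seed=1, n=(4, 4, 4))
        with pytest.raises(ValueError):
            mancova(df)


class TestTukey:
    def test_two_groups_equals_pooled_t(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "group": ["a"] * 10 + ["b"] * 14,
            "y": np.r_[rng.normal(0, 1, 10), rng.normal(0.6, 1, 14)],
        })
        p_tukey = tukey_hsd(df, "y")[("a", "b")]
        p_t = sps.ttest_ind(df[df.group == "a"].y, df[df.group == "b"].y).pvalue
        assert p_tukey == pytest.approx(p_t, abs=2e-4)

    def test_identical_groups_large_n_p_near_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"group": np.repeat(["a", "b", "c"], 2000),
                           "y": rng.normal(size=6000)})
        pvals = tukey_hsd(df, "y")
        assert all(p > 0.05 for p in pvals.values())

    def test_p_ordering_follows_mean_gaps(self):
        # moderate effects keep the adjusted p-values off the lookup floor
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "group": np.repeat(["a", "b", "c"], 25),
            "y": np.r_[rng.normal(0, 1, 25), rng.normal(0.3, 1, 25),
                       rng.normal(0.8, 1, 25)],
        })
        pvals = tukey_hsd(df, "y")
        assert pvals[("a", "c")] < pvals[("a", "b")]
        assert pvals[("b", "c")] < pvals[("a", "b")]

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"group": ["a"] * 5, "y": np.arange(5.0)})
        with pytest.raises(ValueError):
            tukey_hsd(df, "y")


class TestPartialCorrelation:
    def test_equals_residual_regression_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.normal(size=40)
            z = rng.normal(size=40)
            y = 0.4 * x + 0.6 * z + rng.normal(size=40)
            _, _, pr, _ = pearson_and_partial(x, y, z)
            rx = x - np.polyval(np.polyfit(z, x, 1), z)
            ry = y - np.polyval(np.polyfit(z, y, 1), z)
            ref = sps.pearsonr(rx, ry)[0]
            assert pr == pytest.approx(ref, abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        y = 0.5 * x + 0.3 * z + rng.normal(size=30)
        _, _, pr, pp = pearson_and_partial(x, y, z)
        ref = pg.partial_corr(pd.DataFrame({"x": x, "y": y, "z": z}),
                              x="x", y="y", covar="z")
        assert pr == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert pp == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_independent_confounder_leaves_r(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=5000)
        y = 0.5 * x + rng.normal(size=5000)
        z = rng.normal(size=5000)
        r, _, pr, _ = pearson_and_partial(x, y, z)
        assert pr == pytest.approx(r, abs=0.03)

    def test_self_correlation(self):
        x = np.arange(10.0)
        z = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0])
        r, _, pr, _ = pearson_and_partial(x, x, z)
        assert r == pytest.approx(1.0)
        assert pr == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_and_partial([1, 1, 1, 1], [1, 2, 3, 4], [1, 2, 3, 4])


class TestRepeatability:
    @staticmethod
    def _table(vals):
        return pd.DataFrame({"gm_mpf": vals, "pvwgm_mpf": vals,
                             "wm_mpf": vals})

    def test_identical_scans(self):
        t = self._table([6.1, 6.4, 6.6, 6.2, 6.3])
        rep = repeatability(t, t)
        for tissue in rep.per_tissue.values():
            assert tissue["bias"] == 0.0
            assert tissue["loa_high"] - tissue["loa_low"] == 0.0
            assert tissue["cov_percent"] == 0.0

    def test_constant_offset(self):
        t1 = self._table([6.1, 6.4, 6.6, 6.2])
        t2 = t1 + 0.5
        rep = repeatability(t1, t2)
        for tissue in rep.per_tissue.values():
            assert tissue["bias"] == pytest.approx(0.5)
            assert tissue["sd_diff"] == pytest.approx(0.0, abs=1e-12)

    def test_cov_matches_noise_level(self):
        # independent noise sigma per scan: within-subject SD -> sigma
        rng = np.random.default_rng(8)
        sigma, mean, covs = 0.12, 13.0, []
        for _ in range(300):
            base = rng.normal(mean, 0.5, 8)
            t1 = self._table(base + rng.normal(0, sigma, 8))
            t2 = self._table(base + rng.normal(0, sigma, 8))
            covs.append(repeatability(t1, t2).per_tissue["wm_mpf"]["cov_percent"])
        expected = 100.0 * sigma / mean
        assert np.mean(covs) == pytest.approx(expected, rel=0.1)

    def test_too_few_pairs(self):
        t = self._table([6.1, 6.4])
        with pytest.raises(ValueError):
            repeatability(t, t)


class TestCohortStats:
    def test_full_battery_shape(self):
        coh = generate_cohort(seed=6)
        report = cohort_stats(coh)
        assert "three_group" in report.mancova
        assert "patients_vs_controls" in report.mancova
        assert set(report.pairwise) == {"gm_mpf", "pvwgm_mpf", "wm_mpf"}
        # 4 contrasts x 3 tissues
        assert len(report.effects) == 12
        assert any(k.startswith("patients:disease_duration")
                   for k in report.correlations)
        assert any(k.startswith("controls:age") for k in report.correlations)

    def test_control_only_cohort(self):
        coh = generate_cohort(seed=6)
        controls = coh[coh.group == "control"]
        report = cohort_stats(controls)
        assert report.effects == {}
        assert all(k.startswith("controls:age") for k in report.correlations)

    def test_report_roundtrips_through_json(self, tmp_path):
        import json

        coh = generate_cohort(seed=6)
        report = cohort_stats(coh)
        path = tmp_path / "report.json"
        report.to_json(path)
        with open(path) as fh:
            loaded = json.load(fh)
        assert loaded["mancova"]["three_group"]["group"]["wilks_lambda"] == \
            pytest.approx(report.mancova["three_group"]["group"]["wilks_lambda"])
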