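"""Cohort statistical battery: paired tests, ANOVAs, correlations, OLS."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sulcalstrain import stats as cs


class TestPairedCompare:
    def test_identical_pairs_degenerate(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        res = cs.paired_compare(x, x.copy())
        assert res.cohens_d == 0.0
        assert res.p == 1.0

    def test_constructed_positive_effect(self):
        rng = np.random.default_rng(0)
        g = rng.normal(0.08, 0.01, size=40)
        s = g + 0.01 + rng.normal(0.0, 0.001, size=40)
        res = cs.paired_compare(s, g)
        assert res.p < 0.05
        assert res.cohens_d > 2.0  # mean diff 0.01 vs sd ~0.001

    def test_cohens_d_is_paired_variant(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=30)
        s = g + rng.normal(0.5, 0.2, size=30)
        res = cs.paired_compare(s, g)
        d = s - g
        assert res.cohens_d == pytest.approx(d.mean() / d.std(ddof=1))

    def test_wilcoxon_branch_exhaustive_oracle(self):
        """Skewed n=8 differences: V and p match full 2^8 enumeration."""
        gyral = np.zeros(8)
        diffs = np.array([0.02, 0.011, 0.013, 0.016, 5.0, 0.014, -0.01, 0.012])
        sulcal = gyral + diffs
        res = cs.paired_compare(sulcal, gyral)
        assert res.test == "wilcoxon"

        ranks = sps.rankdata(np.abs(diffs))
        V = ranks[diffs > 0].sum()
        assert res.statistic == pytest.approx(V)

        # exact two-sided p by enumerating every sign assignment
        n = 8
        stats_all = [sum(r for r, s in zip(ranks, signs) if s)
                     for signs in itertools.product([0, 1], repeat=n)]
        stats_all = np.array(stats_all)
        mu = ranks.sum() / 2
        p_exact = np.mean(np.abs(stats_all - mu) >= abs(V - mu) - 1e-12)
        assert res.p == pytest.approx(p_exact, abs=1e-9)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            cs.paired_compare(np.ones(2), np.zeros(2))


class TestOneWayAnova:
    def test_equal_values_give_zero_F(self):
        y = np.ones(12)
        g = np.repeat([1, 2, 3], 4)
        res = cs.one_way_anova(y, g)
        assert res.F == 0.0
        assert res.p == 1.0

    def test_textbook_dataset_hand_oracle(self):
        """3 groups x 5 values: F from explicit SSB/SSW sums."""
        groups = {
            1: np.array([6.0, 8.0, 4.0, 5.0, 3.0]),
            2: np.array([8.0, 12.0, 9.0, 11.0, 6.0]),
            3: np.array([13.0, 9.0, 11.0, 8.0, 7.0]),
        }
        y = np.concatenate(list(groups.values()))
        g = np.repeat([1, 2, 3], 5)
        grand = y.mean()
        ssb = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
        ssw = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        F_hand = (ssb / 2) / (ssw / 12)
        res = cs.one_way_anova(y, g)
        assert res.F == pytest.approx(F_hand, rel=1e-12)
        assert (res.df_between, res.df_residual) == (2, 12)

    def test_null_type_one_error_rate(self):
        """Null simulation: rejection rate ~ alpha (binomial bound)."""
        rng = np.random.default_rng(5)
        g = np.repeat([1, 2, 3], [49, 69, 30])
        reps = 300
        rej = sum(cs.one_way_anova(rng.normal(size=148), g).p < 0.05
                  for _ in range(reps))
        rate = rej / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) <= 3 * se

    def test_tukey_adjusted_at_least_unadjusted(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            y = rng.normal(size=30) + np.repeat(rng.normal(size=3, scale=0.5),
                                                10)
            res = cs.one_way_anova(y, np.repeat([1, 2, 3], 10))
            assert (res.posthoc["p_tukey"]
                    >= res.posthoc["p_unadjusted"] - 1e-12).all()

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            cs.one_way_anova(np.arange(4.0), np.array([1, 1, 1, 2]))


class TestRmAnova:
    @staticmethod
    def _long(n_per=12, region_delta=0.0, profile_delta=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for prof in (1, 2, 3):
            for i in range(n_per):
                sid = f"p{prof}_{i}"
                base = 0.09 + profile_delta * (prof == 1) \
                    + rng.normal(0, 0.01)
                noise = rng.normal(0, 0.002, size=2)
                rows.append((sid, prof, "gyral", base + noise[0]))
                rows.append((sid, prof, "sulcal",
                             base + region_delta + noise[1]))
        return pd.DataFrame(rows, columns=["subject", "profile", "region",
                                           "value"])

    def test_constructed_region_effect(self):
        df = self._long(region_delta=0.01)
        res = cs.rm_anova(df["value"], df["profile"], df["region"],
                          df["subject"])
        assert res.p_within < 0.01
        assert res.p_between > 0.05

    def test_constructed_profile_effect(self):
        df = self._long(profile_delta=0.05, seed=1)
        res = cs.rm_anova(df["value"], df["profile"], df["region"],
                          df["subject"])
        assert res.p_between < 0.01

    def test_all_identical_gives_zero_F(self):
        df = self._long()
        df["value"] = 0.25
        res = cs.rm_anova(df["value"], df["profile"], df["region"],
                          df["subject"])
        assert res.F_between == res.F_within == res.F_interaction == 0.0

    def test_transform_recorded(self):
        df = self._long(region_delta=0.01)
        res = cs.rm_anova(df["value"], df["profile"], df["region"],
                          df["subject"])
        assert res.transform in ("sqrt", "log")
        forced = cs.rm_anova(df["value"], df["profile"], df["region"],
                             df["subject"], transform="none")
        assert forced.transform == "none"

    def test_incomplete_subject_rejected(self):
        df = self._long().iloc[:-1]
        with pytest.raises(ValueError):
            cs.rm_anova(df["value"], df["profile"], df["region"],
                        df["subject"])


def cohort_frame(n=148, seed=0, beta=None, noise=1.0):
    """Synthetic cohort table with controllable response construction."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "peak_lin_vel": rng.normal(3.5, 1.5, n).clip(0.1),
        "peak_lin_acc": rng.normal(350, 200, n).clip(1),
        "peak_rot_vel": rng.normal(20, 10, n).clip(0.1),
        "peak_rot_acc": rng.normal(2500, 1200, n).clip(1),
    })
    if beta is None:
        beta = {}
    y = sum(df[k] * v for k, v in beta.items())
    y = (y if np.ndim(y) else np.zeros(n)) + rng.normal(0, noise, n)
    df["sulcal_mean_strain"] = y
    df["sulcal_mean_strain_rate"] = y * 10 + rng.normal(0, noise, n)
    return df


class TestCorrelations:
    def test_exact_linear_relation(self):
        df = cohort_frame(beta={"peak_rot_vel": 2.0}, noise=1e-12)
        out = cs.kinematics_correlations(df, responses=("sulcal_mean_strain",),
                                         predictors=("peak_rot_vel",))
        assert out[0].r2 == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        df = cohort_frame(n=1000, noise=1.0)
        out = cs.kinematics_correlations(df, responses=("sulcal_mean_strain",))
        assert all(c.r2 < 0.02 for c in out)

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0])
        df = pd.DataFrame({"peak_lin_vel": x, "peak_lin_acc": x + 1,
                           "peak_rot_vel": x * 2, "peak_rot_acc": x + 3,
                           "sulcal_mean_strain": y,
                           "sulcal_mean_strain_rate": y})
        r_hand = (np.mean(x * y) - x.mean() * y.mean()) / (
            x.std() * y.std())
        out = cs.kinematics_correlations(df, responses=("sulcal_mean_strain",),
                                         predictors=("peak_lin_vel",))
        assert out[0].r == pytest.approx(r_hand)
        assert out[0].ci_low <= out[0].r2 <= out[0].ci_high

    def test_fisher_ci_coverage(self):
        """CI covers the true r² at ~95% over 500 replicates (rho=0.8)."""
        rng = np.random.default_rng(9)
        n, reps, rho = 148, 500, 0.8
        hits = 0
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rho * x + np.sqrt(1 - rho ** 2) * rng.normal(size=n)
            r, _ = sps.pearsonr(x, y)
            lo, hi = cs._fisher_ci_r2(r, n)
            hits += lo <= rho ** 2 <= hi
        assert abs(hits / reps - 0.95) <= 0.03

    def test_zero_variance_rejected(self):
        df = cohort_frame(n=20)
        df["peak_rot_vel"] = 5.0
        with pytest.raises(ValueError, match="zero-variance"):
            cs.kinematics_correlations(df)


class TestRegression:
    def test_parameter_recovery(self):
        df = cohort_frame(n=200, beta={"peak_rot_vel": 3.0}, noise=0.5)
        res = cs.kinematics_regression(df, "sulcal_mean_strain")
        p = res.params.set_index("predictor")
        assert p.loc["peak_rot_vel", "ci_low"] <= 3.0 \
            <= p.loc["peak_rot_vel", "ci_high"]
        for other in ("peak_lin_vel", "peak_lin_acc", "peak_rot_acc"):
            assert p.loc[other, "ci_low"] <= 0.0 <= p.loc[other, "ci_high"]

    def test_constant_response(self):
        df = cohort_frame(n=50, noise=1e-15)
        df["sulcal_mean_strain"] = 1.0
        res = cs.kinematics_regression(df, "sulcal_mean_strain")
        betas = res.params.set_index("predictor")["beta"]
        assert abs(betas.drop("const")).max() < 1e-8
        assert res.r2 == pytest.approx(0.0, abs=1e-6)

    def test_exact_linear_zero_noise(self):
        df = cohort_frame(n=60, beta={"peak_rot_vel": 1.5,
                                      "peak_lin_vel": -0.2}, noise=1e-13)
        res = cs.kinematics_regression(df, "sulcal_mean_strain")
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        p = res.params.set_index("predictor")
        width = p.loc["peak_rot_vel", "ci_high"] - p.loc["peak_rot_vel",
                                                         "ci_low"]
        assert width < 1e-9

    def test_collinearity_warning_recorded(self):
        df = cohort_frame(n=40, beta={"peak_rot_vel": 1.0}, noise=0.1)
        df["peak_rot_acc"] = df["peak_rot_vel"] * 100.0
        res = cs.kinematics_regression(df, "sulcal_mean_strain")
        assert res.collinearity_warning
        assert np.isfinite(res.params["beta"]).all()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            cs.kinematics_regression(cohort_frame(n=6), "sulcal_mean_strain")


class TestReport:
    def test_degenerate_columns_flagged(self):
        df = cohort_frame(n=12)
        for col in ("p90_strain", "p90_strain_rate", "gyral_mean_strain"):
            df[col] = 0.0
        df["sulcal_mean_strain"] = 0.0
        df["sulcal_mean_strain_rate"] = 0.0
        df["gyral_mean_strain_rate"] = 0.0
        df["profile"] = np.repeat([1, 2, 3], 4)
        df["event_id"] = [f"e{i}" for i in range(12)]
        out = cs.cohort_report(df)
        assert "p90_strain" in out["degenerate"]
        assert "markdown" in out

    def test_full_report_on_healthy_cohort(self):
        df = cohort_frame(n=45, beta={"peak_rot_vel": 0.004}, noise=0.01)
        df["sulcal_mean_strain"] = df["sulcal_mean_strain"].abs() + 0.01
        df["gyral_mean_strain"] = df["sulcal_mean_strain"] * 0.9
        df["sulcal_mean_strain_rate"] = df["sulcal_mean_strain"] * 100
        df["gyral_mean_strain_rate"] = df["gyral_mean_strain"] * 100
        df["p90_strain"] = df["sulcal_mean_strain"] * 1.2
        df["p90_strain_rate"] = df["p90_strain"] * 100
        df["profile"] = np.repeat([1, 2, 3], 15)
        df["event_id"] = [f"e{i}" for i in range(45)]
        out = cs.cohort_report(df)
        assert "anova" in out and "p90_strain" in out["anova"]
        assert "paired_strain" in out
        assert "rm_anova_strain" in out
        assert "correlations" in out
        assert "regression" in out
        assert "F(" in out["markdown"]
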