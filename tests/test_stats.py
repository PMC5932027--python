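"""Cohort statistics: transforms, screening, group tests, correlations."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ironforms.stats import (apply_transforms, braak_stratify,
                             compare_correlations, correlogram, group_tests,
                             partial_correlation, screen_outliers,
                             spearman_with_p)
from ironforms.synthetic import (VARIABLES, cohort_to_frame,
                                 default_cohort_spec, generate_cohort)


class TestTransforms:
    def test_values(self):
        t = apply_transforms(pd.DataFrame({"fe3": [10.0, 1.0],
                                           "magnetite": [0.0, 900.0]}))
        np.testing.assert_allclose(t.fe3, [1.0, 0.0])
        np.testing.assert_allclose(t.magnetite, [2.0, 3.0])

    def test_other_columns_untouched(self):
        df = pd.DataFrame({"fe3": [1.0], "ferrihydrite": [300.0]})
        t = apply_transforms(df)
        assert t.ferrihydrite.iloc[0] == 300.0

    def test_nonpositive_fe3_rejected(self):
        with pytest.raises(ValueError):
            apply_transforms(pd.DataFrame({"fe3": [0.0]}))


class TestOutlierScreen:
    def test_flags_gross_outlier(self):
        kept, flags = screen_outliers(np.array([1.0, 2.0, 3.0, 100.0]))
        assert flags.tolist() == [False, False, False, True]
        np.testing.assert_array_equal(kept, [1.0, 2.0, 3.0])

    def test_all_equal_never_flagged(self):
        kept, flags = screen_outliers(np.full(8, 3.14))
        assert not flags.any()
        assert kept.size == 8

    def test_clean_normal_rarely_flagged(self):
        """On clean normal samples the family-wise flag rate stays near the
        nominal 5%, so >= 95% of seeds come through untouched."""
        rng = np.random.default_rng(1234)
        untouched = sum(
            not screen_outliers(rng.standard_normal(20))[1].any()
            for _ in range(1000))
        assert untouched >= 935  # ~nominal with Monte-Carlo slack

    def test_at_most_two_removed(self):
        x = np.concatenate([np.zeros(10), [50.0, 60.0, 70.0]])
        x[:10] = np.random.default_rng(0).normal(0, 0.1, 10)
        _, flags = screen_outliers(x)
        assert flags.sum() <= 2

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            screen_outliers(np.array([1.0, 2.0, 3.0]))


class TestGroupTests:
    def test_identical_groups(self):
        df = pd.DataFrame({
            "group": ["AD"] * 4 + ["control"] * 4,
            "ferrihydrite": [1.0, 2.0, 3.0, 4.0] * 2,
        })
        res = group_tests(df, variables=("ferrihydrite",))
        t = res[res.test == "mean_student"].iloc[0]
        assert t.statistic == 0.0 and t.p == 1.0

    def test_zero_variance_reports_na(self):
        df = pd.DataFrame({
            "group": ["AD"] * 3 + ["control"] * 3,
            "ferrihydrite": [1.0] * 3 + [2.0] * 3,
        })
        with pytest.warns(UserWarning, match="zero"):
            res = group_tests(df, variables=("ferrihydrite",))
        assert np.isnan(res[res.test == "mean_student"].iloc[0].p)

    def test_power_on_published_separation(self):
        """Groups drawn at 5x the published sizes from the ferrihydrite
        group moments separate at p < 0.05 in > 95% of seeds."""
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(200):
            a = rng.normal(381.12, 178.97, 110)
            b = rng.normal(240.84, 98.02, 70)
            df = pd.DataFrame({"group": ["AD"] * 110 + ["control"] * 70,
                               "ferrihydrite": np.r_[a, b]})
            res = group_tests(df, variables=("ferrihydrite",))
            hits += res[res.test == "mean_student"].iloc[0].p < 0.05
        assert hits > 190

    def test_demographics_present(self):
        df = cohort_to_frame(generate_cohort(default_cohort_spec(seed=4)))
        res = group_tests(df)
        assert {"mann_whitney", "chi_square"} <= set(res.test)
        assert res.p.dropna().between(0, 1).all()

    def test_brown_forsythe_is_median_centered(self, rng):
        """Our variance test equals one-way ANOVA on |x - group median|."""
        a, b = rng.standard_normal(20), 2 * rng.standard_normal(15)
        df = pd.DataFrame({"group": ["AD"] * 20 + ["control"] * 15,
                           "ferrihydrite": np.r_[a, b]})
        res = group_tests(df, variables=("ferrihydrite",))
        w = res[res.test == "variance_brown_forsythe"].iloc[0]
        da = np.abs(a - np.median(a))
        db = np.abs(b - np.median(b))
        f_oracle, p_oracle = sps.f_oneway(da, db)
        np.testing.assert_allclose(w.statistic, f_oracle, rtol=1e-10)
        np.testing.assert_allclose(w.p, p_oracle, rtol=1e-10)


class TestCorrelogram:
    def test_monotone_pair(self):
        df = pd.DataFrame({"group": ["AD"] * 12,
                           "fe3": np.arange(12.0) + 1,
                           "flr": np.exp(np.arange(12.0))})
        rho, p = correlogram(df, group="AD", variables=("fe3", "flr"))
        assert rho.loc["fe3", "flr"] == 1.0

    def test_independent_columns_near_zero(self, rng):
        df = pd.DataFrame({"group": ["AD"] * 5000,
                           "fe3": rng.random(5000),
                           "flr": rng.random(5000)})
        rho, _ = correlogram(df, group="AD", variables=("fe3", "flr"))
        assert abs(rho.loc["fe3", "flr"]) < 0.05

    def test_constant_column_na(self):
        df = pd.DataFrame({"group": ["AD"] * 8, "fe3": np.ones(8),
                           "flr": np.arange(8.0)})
        rho, p = correlogram(df, group="AD", variables=("fe3", "flr"))
        assert np.isnan(rho.loc["fe3", "flr"])

    def test_target_recovery_at_n2000(self):
        spec = default_cohort_spec(n_ad=2000, n_control=3, seed=8)
        df = cohort_to_frame(generate_cohort(spec))
        rho, _ = correlogram(df, group="AD")
        assert abs(rho.loc["fe3", "flr"] - 0.825) < 0.05

    def test_symmetry_and_diagonal(self):
        df = cohort_to_frame(generate_cohort(default_cohort_spec(seed=4)))
        rho, p = correlogram(df, group="AD")
        np.testing.assert_allclose(rho.values, rho.values.T)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_small_n_uses_exact_permutation(self, rng):
        """Below n = 10 the p-value comes from full enumeration: for a
        perfectly monotone pair of 5 it equals 2/5! * 2 ... checked against
        the known exact value 1/60."""
        x = np.arange(5.0)
        y = x ** 3
        rho, p = spearman_with_p(x, y)
        np.testing.assert_allclose(rho, 1.0, atol=1e-12)
        np.testing.assert_allclose(p, 2 / 120)  # only +/- identity perms

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(30)
        y = rng.random(30)
        r1, _ = spearman_with_p(x, y)
        r2, _ = spearman_with_p(np.exp(3 * x), y ** 3)
        np.testing.assert_allclose(r1, r2, atol=1e-12)


class TestCompareCorrelations:
    def test_published_cases(self):
        """The two near-threshold group comparisons of the ferrihydrite
        pairs reproduce p = 0.076 and 0.079."""
        c1 = compare_correlations(-0.629, 18, -0.908, 11)
        c2 = compare_correlations(-0.729, 18, -0.935, 11)
        assert abs(c1.p - 0.076) < 1e-3
        assert abs(c2.p - 0.079) < 1e-3

    def test_equal_correlations(self):
        c = compare_correlations(0.4, 20, 0.4, 20)
        assert c.z_diff == 0.0 and c.p == 1.0

    @settings(max_examples=30, deadline=None)
    @given(r1=st.floats(-0.95, 0.95), r2=st.floats(-0.95, 0.95),
           n1=st.integers(5, 60), n2=st.integers(5, 60))
    def test_antisymmetry(self, r1, r2, n1, n2):
        a = compare_correlations(r1, n1, r2, n2)
        b = compare_correlations(r2, n2, r1, n1)
        np.testing.assert_allclose(a.z_diff, -b.z_diff, atol=1e-12)
        np.testing.assert_allclose(a.p, b.p, atol=1e-12)

    def test_degenerate_rho_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations(1.0, 10, 0.5, 10)
        with pytest.raises(ValueError):
            compare_correlations(0.5, 3, 0.5, 10)


class TestPartialCorrelation:
    def test_reduces_to_plain_when_control_independent(self, rng):
        n = 4000
        x = rng.standard_normal(n)
        y = 0.6 * x + 0.8 * rng.standard_normal(n)
        z = rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        r_part, _ = partial_correlation(df, "x", "y", "z")
        r_plain = sps.spearmanr(x, y)[0]
        assert abs(r_part - r_plain) < 0.03

    def test_collinear_control_rejected(self, rng):
        y = rng.standard_normal(50)
        df = pd.DataFrame({"x": rng.standard_normal(50), "y": y, "z": y})
        with pytest.raises(ValueError):
            partial_correlation(df, "x", "y", "z")

    def test_matches_pingouin(self, rng):
        """Cross-check the recursion formula against an independent
        implementation (pingouin's rank-based partial correlation)."""
        pingouin = pytest.importorskip("pingouin")
        n = 60
        x = rng.standard_normal(n)
        z = 0.5 * x + rng.standard_normal(n)
        y = -0.4 * z + rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        r, p = partial_correlation(df, "x", "y", "z")
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z",
                                    method="spearman")
        np.testing.assert_allclose(r, ref["r"].iloc[0], atol=1e-10)
        np.testing.assert_allclose(p, ref["p_val"].iloc[0], atol=1e-8)

    def test_sign_pattern_of_pooled_panel(self):
        """Pooled synthetic cohorts reproduce the published partial-
        correlation sign pattern: Fe(III)~FLR | ferrihydrite positive,
        ferrihydrite~FLR | Fe(III) negative, Fe(III)~ferrihydrite | FLR
        near zero (smaller in magnitude than both)."""
        hits = 0
        for seed in range(20):
            spec = default_cohort_spec(n_ad=250, n_control=250, seed=seed)
            df = cohort_to_frame(generate_cohort(spec))
            r_pos, _ = partial_correlation(df, "fe3", "flr", "ferrihydrite")
            r_neg, _ = partial_correlation(df, "ferrihydrite", "flr", "fe3")
            r_nul, _ = partial_correlation(df, "fe3", "ferrihydrite", "flr")
            ok = (r_pos > 0 and r_neg < 0
                  and abs(r_nul) < min(r_pos, abs(r_neg)))
            hits += ok
        assert hits >= 18


class TestBraakStratify:
    def test_controls_pooled(self):
        df = pd.DataFrame({
            "group": ["control"] * 3 + ["AD"] * 3,
            "braak": [0, 2, 3, 4, 5, 6],
            "ferrihydrite": [200.0, 210, 220, 300, 350, 400],
        })
        res = braak_stratify(df, variables=("ferrihydrite",))
        assert res.stratum.tolist() == ["4", "5", "6", "<=3"]
        pooled = res[res.stratum == "<=3"].iloc[0]
        assert pooled.n == 3
        np.testing.assert_allclose(pooled.ferrihydrite_mean, 210.0)

    def test_empty_stratum_omitted(self):
        df = pd.DataFrame({
            "group": ["control"] * 2 + ["AD"] * 2,
            "braak": [1, 2, 4, 4],
            "ferrihydrite": [1.0, 2.0, 3.0, 4.0],
        })
        res = braak_stratify(df, variables=("ferrihydrite",))
        assert set(res.stratum) == {"<=3", "4"}

    def test_unknown_stage_rejected(self):
        df = pd.DataFrame({"group": ["AD"], "braak": [9],
                           "ferrihydrite": [1.0]})
        with pytest.raises(ValueError):
            braak_stratify(df, variables=("ferrihydrite",))

    def test_monotone_on_severity_cohort(self):
        spec = default_cohort_spec(n_ad=300, n_control=200, seed=6)
        df = cohort_to_frame(generate_cohort(spec))
        res = braak_stratify(df).set_index("stratum")
        means = [res.loc[s, "ferrihydrite_mean"] for s in ("4", "5", "6")]
        assert means[0] < means[1] < means[2]


def test_missing_moments_excluded_pairwise():
    """SNR-discarded magnetite moments (NaN) drop out of the correlogram
    pair by pair without affecting other pairs."""
    spec = default_cohort_spec(seed=9)
    df = cohort_to_frame(generate_cohort(spec))
    df.loc[df.index[:5], "magnetite_moment"] = np.nan
    rho_full, _ = correlogram(df, group="AD",
                              variables=("fe3", "ferrihydrite"))
    rho_miss, _ = correlogram(df, group="AD",
                              variables=("fe3", "ferrihydrite",
                                         "magnetite_moment"))
    np.testing.assert_allclose(rho_full.loc["fe3", "ferrihydrite"],
                               rho_miss.loc["fe3", "ferrihydrite"])
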