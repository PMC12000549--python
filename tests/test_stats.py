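"""Statistical battery: exact small-sample oracles and recovery checks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dtialps import stats as cs
from dtialps.errors import DegenerateDesignError, InputError, SchemaError
from dtialps.synthetic import CohortConfig, generate_cohort_metadata


class TestAgeAdjustment:
    def test_exact_line(self):
        """Ages (50, 60, 70) with indices (1.4, 1.3, 1.2): beta = -0.01/yr."""
        model = cs.fit_age_adjustment([1.4, 1.3, 1.2], [50.0, 60.0, 70.0])
        assert model.beta == pytest.approx(-0.01, abs=1e-12)
        assert model.age_mean == pytest.approx(60.0)

    def test_null_slope_for_age_independent_index(self, rng):
        ages = rng.uniform(40, 80, 4000)
        raw = 1.3 + rng.normal(0, 0.1, 4000)
        model = cs.fit_age_adjustment(raw, ages)
        assert abs(model.beta) < 3 * 0.1 / (ages.std() * np.sqrt(4000))

    def test_adjustment_identity_at_mean_age(self):
        model = cs.AdjustmentModel(beta=-0.01, age_mean=60.0)
        assert cs.apply_age_adjustment(1.3, 60.0, model) == pytest.approx(1.3)

    def test_direct_substitution(self):
        model = cs.AdjustmentModel(beta=-0.01, age_mean=60.0)
        assert cs.apply_age_adjustment(1.3, 70.0, model) == pytest.approx(1.4)

    def test_zero_residual_slope_after_adjustment(self):
        """Within the fitting sample the adjusted index is age-flat."""
        rng = np.random.default_rng(4)
        ages = rng.uniform(45, 85, 300)
        raw = 1.5 - 0.008 * ages + rng.normal(0, 0.1, 300)
        model = cs.fit_age_adjustment(raw, ages)
        adj = cs.apply_age_adjustment(raw, ages, model)
        assert abs(np.polyfit(ages, adj, 1)[0]) < 1e-12

    def test_recovery_of_simulated_beta(self):
        cfg = CohortConfig(n_per_group={"PD": 50, "iRBD": 50, "HC": 800},
                           age_slope_beta=-0.008, seed=6)
        table = generate_cohort_metadata(cfg)
        hc = table[table["group"] == "HC"]
        model = cs.fit_age_adjustment(hc["latent_alps"].to_numpy(), hc["age"].to_numpy())
        resid_sd = cfg.noise_sd_index
        se = resid_sd / (hc["age"].std() * np.sqrt(len(hc)))
        assert abs(model.beta - (-0.008)) < 3 * se

    def test_degenerate_designs_rejected(self):
        with pytest.raises(DegenerateDesignError):
            cs.fit_age_adjustment([1.0, 1.1], [50.0, 60.0])
        with pytest.raises(DegenerateDesignError):
            cs.fit_age_adjustment([1.0, 1.1, 1.2], [60.0, 60.0, 60.0])


class TestAncova:
    def test_df_accounting_at_study_sizes(self):
        """N = 184, 3 groups, 1 covariate gives df = (2, 180)."""
        rng = np.random.default_rng(0)
        groups = np.repeat(["PD", "iRBD", "HC"], [79, 57, 48])
        y = rng.normal(size=184)
        cov = rng.integers(0, 2, 184).astype(float)
        res = cs.ancova_oneway(y, groups, cov)
        assert (res.df1, res.df2) == (2, 180)

    def test_identical_groups_yield_null_f(self, rng):
        y = np.tile(rng.normal(size=50), 2)
        groups = np.repeat(["A", "B"], 50)
        res = cs.ancova_oneway(y, groups)
        assert res.f == pytest.approx(0.0, abs=1e-20)
        assert res.p == pytest.approx(1.0)
        assert res.partial_eta_sq == pytest.approx(0.0, abs=1e-20)

    def test_nine_subject_fixture_matches_hand_computed_ss(self):
        """Explicit sums-of-squares oracle on a 3x3 fixture with a covariate.

        The oracle projects y onto [1, cov] and onto [1, cov, dummies] with
        raw normal-equation algebra and compares every derived quantity.
        """
        y = np.array([1.0, 1.2, 1.1, 1.5, 1.7, 1.6, 2.0, 2.2, 2.4])
        groups = np.repeat(["a", "b", "c"], 3)
        cov = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0, 0.0, 1.0, 2.0])

        def rss(X):
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            r = y - X @ beta
            return r @ r

        X_red = np.column_stack([np.ones(9), cov])
        X_full = np.column_stack(
            [np.ones(9), cov, (groups == "b").astype(float), (groups == "c").astype(float)]
        )
        ss_group = rss(X_red) - rss(X_full)
        ss_error = rss(X_full)
        df1, df2 = 2, 9 - 3 - 1
        f_oracle = (ss_group / df1) / (ss_error / df2)

        res = cs.ancova_oneway(y, groups, cov)
        assert res.ss_group == pytest.approx(ss_group, rel=1e-12)
        assert res.ss_error == pytest.approx(ss_error, rel=1e-12)
        assert res.f == pytest.approx(f_oracle, rel=1e-12)
        assert res.partial_eta_sq == pytest.approx(ss_group / (ss_group + ss_error), rel=1e-12)

    def test_matches_pingouin_ancova(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        n = 60
        df = pd.DataFrame({
            "y": rng.normal(size=n),
            "g": rng.choice(["PD", "iRBD", "HC"], n),
            "cov": rng.normal(size=n),
        })
        ours = cs.ancova_oneway(df["y"].to_numpy(), df["g"].to_numpy(), df["cov"].to_numpy())
        ref = pingouin.ancova(data=df, dv="y", between="g", covar="cov")
        row = ref[ref["Source"] == "g"].iloc[0]
        assert ours.f == pytest.approx(row["F"], rel=1e-6)
        assert ours.p == pytest.approx(row["p_unc"], rel=1e-6)
        assert ours.partial_eta_sq == pytest.approx(row["np2"], rel=1e-6)

    def test_lsd_pairwise_p_unadjusted(self, rng):
        y = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30), rng.normal(0, 1, 30)])
        groups = np.repeat(["a", "b", "c"], 30)
        res = cs.ancova_oneway(y, groups)
        assert set(res.lsd_pairwise_p) == set(itertools.combinations(["a", "b", "c"], 2))
        assert res.lsd_pairwise_p[("a", "b")] < 0.05
        assert all(0 <= p <= 1 for p in res.lsd_pairwise_p.values())

    def test_type_one_error_calibrated_under_null(self):
        """Group-effect rejection rate at alpha 0.05 is 5% +/- 1% over 2000
        null simulations with an active covariate."""
        rng = np.random.default_rng(2024)
        n_sims, n = 2000, 60
        groups = np.repeat(["a", "b", "c"], n // 3)
        rejections = 0
        for _ in range(n_sims):
            cov = rng.normal(size=n)
            y = 0.5 * cov + rng.normal(size=n)  # covariate active, no group effect
            res = cs.ancova_oneway(y, groups, cov)
            rejections += res.p < 0.05
        rate = rejections / n_sims
        assert abs(rate - 0.05) < 0.01

    def test_singular_design_rejected(self):
        y = np.arange(6.0)
        groups = np.repeat(["a", "b"], 3)
        cov = (groups == "b").astype(float)  # collinear with the dummy
        with pytest.raises(DegenerateDesignError):
            cs.ancova_oneway(y, groups, cov)


class TestPartialEtaSquared:
    @pytest.mark.parametrize(
        "f, df1, df2, expected",
        [(4.081, 2, 180, 0.043), (6.448, 2, 180, 0.067), (0.0, 2, 180, 0.0)],
    )
    def test_values_from_f(self, f, df1, df2, expected):
        assert round(cs.partial_eta_squared_from_f(f, df1, df2), 3) == expected

    def test_agrees_with_ss_route_exactly(self, rng):
        y = np.concatenate([rng.normal(0, 1, 20), rng.normal(0.7, 1, 20)])
        groups = np.repeat(["a", "b"], 20)
        cov = rng.normal(size=40)
        res = cs.ancova_oneway(y, groups, cov)
        direct = res.ss_group / (res.ss_group + res.ss_error)
        assert cs.partial_eta_squared_from_f(res.f, res.df1, res.df2) == pytest.approx(
            direct, abs=1e-12
        )


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariate_effect(self, rng):
        x = rng.normal(size=5000)
        y = 0.5 * x + rng.normal(size=5000)
        cov = rng.normal(size=5000)  # independent of both
        r_partial = cs.partial_correlation(x, y, cov).r
        r_pearson = np.corrcoef(x, y)[0, 1]
        assert r_partial == pytest.approx(r_pearson, abs=0.02)

    def test_df_at_study_size(self, rng):
        x, y, cov = rng.normal(size=(3, 132))
        res = cs.partial_correlation(x, y, cov)
        assert res.df == 129  # n - 2 - 1 covariate

    def test_equals_residualize_then_correlate_oracle(self, rng):
        n = 25
        cov = rng.normal(size=(n, 2))
        x = cov @ [0.5, -0.2] + rng.normal(size=n)
        y = cov @ [-0.3, 0.4] + rng.normal(size=n)
        res = cs.partial_correlation(x, y, cov)
        X = np.column_stack([np.ones(n), cov])
        H = X @ np.linalg.solve(X.T @ X, X.T)
        rx, ry = x - H @ x, y - H @ y
        r_oracle = (rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry))
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.df == n - 4

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 40
        df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["x", "y", "c"])
        df["y"] += 0.6 * df["x"]
        ours = cs.partial_correlation(df["x"].to_numpy(), df["y"].to_numpy(), df["c"].to_numpy())
        ref = pingouin.partial_corr(data=df, x="x", y="y", covar="c")
        assert ours.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert ours.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_constant_residuals_rejected(self):
        with pytest.raises(DegenerateDesignError):
            cs.partial_correlation(np.ones(10), np.arange(10.0))


class TestPairedComparison:
    def test_summary_statistic_effect_size(self):
        """Means 1.30/1.23 with SDs 0.18/0.16 give d = 0.41 to 2 dp."""
        d = cs.cohens_d_from_summary(1.30, 0.18, 1.23, 0.16)
        assert round(d, 2) == 0.41

    def test_identical_series_null(self, rng):
        a = rng.normal(size=30)
        res = cs.paired_t_and_cohens_d(a, a.copy())
        assert res["t"] == 0.0
        assert res["d"] == 0.0
        assert res["p"] == 1.0

    def test_df_is_n_minus_one(self, rng):
        a = rng.normal(1.30, 0.18, 184)
        b = rng.normal(1.23, 0.16, 184)
        res = cs.paired_t_and_cohens_d(a, b)
        assert res["df"] == 183

    def test_dz_variant_uses_difference_sd(self, rng):
        a = rng.normal(size=50)
        b = a - 0.2 + rng.normal(0, 0.1, 50)
        res = cs.paired_t_and_cohens_d(a, b, d_variant="dz")
        diff = a - b
        assert res["d"] == pytest.approx(diff.mean() / diff.std(ddof=1), rel=1e-12)


class TestBlandAltman:
    def test_identical_series(self, rng):
        a = rng.normal(size=20)
        res = cs.bland_altman(a, a.copy())
        assert res.bias == 0.0 and res.sd == 0.0 and res.fraction_outside == 0.0

    def test_two_point_difference_closed_form(self):
        """Alternating +/-0.1 differences at n = 100: SD = sqrt(0.01*100/99)."""
        base = np.linspace(1.0, 2.0, 100)
        diffs = np.where(np.arange(100) % 2 == 0, 0.1, -0.1)
        res = cs.bland_altman(base + diffs, base)
        assert res.bias == pytest.approx(0.0, abs=1e-12)
        assert res.sd == pytest.approx(np.sqrt(100 * 0.01 / 99), rel=1e-9)
        assert res.loa_high == pytest.approx(1.96 * res.sd, rel=1e-9)

    def test_gaussian_fraction_outside_limits(self, rng):
        """For Gaussian differences ~4.6% of pairs fall outside the limits."""
        n = 200_000
        a = rng.normal(size=n)
        b = a + rng.normal(0, 0.1, n)
        res = cs.bland_altman(a, b)
        assert res.fraction_outside == pytest.approx(0.046, abs=0.004)

    def test_proportional_bias_recovered(self, rng):
        n = 184
        mean_level = rng.uniform(1.0, 1.6, n)
        a = mean_level + 0.2 * mean_level + rng.normal(0, 0.02, n)
        b = mean_level - 0.0 + rng.normal(0, 0.02, n)
        res = cs.bland_altman(a, b)
        # slope of (a-b) on (a+b)/2 ~ 0.2/(1+0.1) for this construction
        assert res.slope == pytest.approx(0.2 / 1.1, abs=0.05)
        assert res.slope_p < 0.05

    def test_percent_mode_and_zero_mean_error(self):
        a = np.array([1.0, 2.0, 1.0])
        b = np.array([1.0, 1.0, -1.0])
        res = cs.bland_altman(a[:2], b[:2], mode="percent")
        assert res.mode == "percent"
        with pytest.raises(InputError):
            cs.bland_altman(a, b, mode="percent")


class TestMatching:
    def _roster(self, n, age_offset=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, off in (("PD", 0.0), ("iRBD", age_offset), ("HC", age_offset)):
            for i in range(n):
                rows.append({
                    "subject_id": f"{g}-{i}", "group": g,
                    "age": 60 + rng.uniform(-5, 5) + off,
                    "sex": "M" if rng.random() < 0.5 else "F",
                })
        return pd.DataFrame(rows)

    def test_identical_groups_fully_matched(self):
        df = self._roster(8)
        df["sex"] = "M"
        df["age"] = np.tile(np.arange(8.0), 3) + 60
        out = cs.match_case_control(df, seed=3)
        assert (out.groupby("group").size() == 8).all()

    def test_disjoint_ages_cannot_match(self):
        df = self._roster(6, age_offset=20.0)
        with pytest.raises(InputError):
            cs.match_case_control(df, seed=1)

    def test_deterministic_given_seed(self):
        df = self._roster(10, seed=5)
        a = cs.match_case_control(df, seed=9)
        b = cs.match_case_control(df, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_never_exceeds_exhaustive_maximum(self):
        """Greedy triplet count <= brute-force maximum on small rosters."""
        for seed in range(6):
            df = self._roster(5, seed=seed)
            best = cs.max_triplet_count(df)
            try:
                out = cs.match_case_control(df, seed=seed)
                greedy = len(out) // 3
            except InputError:
                greedy = 0
            assert greedy <= best
            if best == 0:
                assert greedy == 0

    def test_matched_pairs_respect_tolerance_and_sex(self):
        df = self._roster(12, seed=2)
        out = cs.match_case_control(df, age_tolerance=8.0, seed=4)
        n = len(out) // 3
        # reconstruct triplets by re-running the deterministic matcher logic:
        # every matched non-case subject must have a same-sex case within 8 y
        cases = out[out["group"] == "PD"]
        for g in ("iRBD", "HC"):
            for _, row in out[out["group"] == g].iterrows():
                compatible = cases[
                    (cases["sex"] == row["sex"])
                    & ((cases["age"] - row["age"]).abs() <= 8.0)
                ]
                assert len(compatible) > 0
        assert (out.groupby("group").size() == n).all()


class TestUpdrsSubscores:
    def _items(self, values: dict[int, int], n=1):
        data = {f"updrs3_item{i}": [values.get(i, 0)] * n for i in range(1, 19)}
        return pd.DataFrame(data)

    def test_all_zero(self):
        out = cs.updrs_subscores(self._items({}))
        assert (out.to_numpy() == 0).all()

    def test_rigidity_is_item_three(self):
        out = cs.updrs_subscores(self._items({3: 4}))
        assert out.loc[0, "rigidity"] == 4
        assert out.loc[0, ["tremor", "bradykinesia", "axial"]].sum() == 0

    def test_item_nine_counted_in_both_bradykinesia_and_axial(self):
        out = cs.updrs_subscores(self._items({9: 2}))
        assert out.loc[0, "bradykinesia"] == 2
        assert out.loc[0, "axial"] == 2

    def test_random_table_matches_spreadsheet_oracle(self, rng):
        n = 40
        items = pd.DataFrame(
            rng.integers(0, 5, size=(n, 18)),
            columns=[f"updrs3_item{i}" for i in range(1, 19)],
        )
        out = cs.updrs_subscores(items)
        sets = {"tremor": [15, 16, 17, 18], "bradykinesia": [2, 4, 5, 6, 7, 8, 9, 14],
                "rigidity": [3], "axial": [1, 9, 10, 11, 12, 13]}
        for name, idx in sets.items():
            oracle = sum(items[f"updrs3_item{i}"] for i in idx)
            assert (out[name] == oracle).all()

    def test_missing_column_raises_schema_error(self):
        items = self._items({}).drop(columns=["updrs3_item7"])
        with pytest.raises(SchemaError):
            cs.updrs_subscores(items)


class TestHemisphereAsymmetry:
    def test_all_ties_raise(self):
        with pytest.raises(InputError):
            cs.hemisphere_asymmetry_test([1.3, 1.2], [1.2, 1.3], [0.0, -1.0], [0.0, -1.0])

    def test_symmetric_alps_gives_null_t(self, rng):
        n = 50
        alps = rng.normal(1.3, 0.1, n)
        sbr_l = rng.normal(-1, 1, n)
        sbr_r = sbr_l + rng.choice([-0.5, 0.5], n)
        res = cs.hemisphere_asymmetry_test(alps, alps, sbr_l, sbr_r)
        assert res["t"] == 0.0

    def test_lateralized_effect_recovered(self, rng):
        """ALPS 0.05 lower on the more denervated side is detected at n=100."""
        n = 100
        base = rng.normal(1.3, 0.1, n)
        sbr_l = rng.normal(-1, 1, n)
        sbr_r = sbr_l + rng.choice([-1.0, 1.0], n) * rng.uniform(0.2, 1.0, n)
        more_is_left = sbr_l < sbr_r
        noise = rng.normal(0, 0.05, n)
        alps_l = np.where(more_is_left, base - 0.05, base) + noise
        alps_r = np.where(more_is_left, base, base - 0.05) - noise
        res = cs.hemisphere_asymmetry_test(alps_l, alps_r, sbr_l, sbr_r)
        diff_mean = -0.05
        se = 3 * 0.1 / np.sqrt(n)
        got = (res["t"] * np.sqrt(2) * 0.05) / np.sqrt(n)  # rough scale check only
        assert res["p"] < 0.05
        assert res["n"] == n


class TestDescribeCohort:
    def test_two_identical_groups_null(self, rng):
        half = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(40)],
            "group": "A",
            "age": rng.uniform(50, 70, 40),
            "sex": np.where(rng.random(40) < 0.5, "M", "F"),
        })
        other = half.copy()
        other["group"] = "B"
        other["subject_id"] = [f"t{i}" for i in range(40)]
        out = cs.describe_cohort(pd.concat([half, other]), score_columns=())
        assert out["tests"]["sex_chi2"]["p"] == pytest.approx(1.0)
        assert out["tests"]["age_anova"]["f"] == pytest.approx(0.0, abs=1e-20)

    def test_chi_square_matches_contingency_formula(self):
        """30/10 vs 10/30 males/females gives the hand-computed chi2 = 20."""
        rows = []
        for g, males, females in (("A", 30, 10), ("B", 10, 30)):
            rows += [{"group": g, "sex": "M", "age": 60.0}] * males
            rows += [{"group": g, "sex": "F", "age": 60.0}] * females
        df = pd.DataFrame(rows)
        df["subject_id"] = [f"s{i}" for i in range(len(df))]
        df["age"] += np.linspace(-5, 5, len(df))
        out = cs.describe_cohort(df, score_columns=())
        assert out["tests"]["sex_chi2"]["chi2"] == pytest.approx(20.0, rel=1e-12)

    def test_age_difference_detected_at_study_sizes(self):
        """iRBD-vs-PD age gap (66.5 vs 59.5) is significant at study n."""
        cfg = CohortConfig(seed=14)
        table = generate_cohort_metadata(cfg)
        out = cs.describe_cohort(table)
        assert out["tests"]["age_anova"]["p"] < 0.05
        assert out["groups"]["iRBD"]["age_mean"] > out["groups"]["PD"]["age_mean"]

    def test_single_group_rejected(self):
        df = pd.DataFrame({"group": ["A"] * 5, "age": range(5), "sex": ["M"] * 5,
                           "subject_id": [f"s{i}" for i in range(5)]})
        with pytest.raises(DegenerateDesignError):
            cs.describe_cohort(df, score_columns=())
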