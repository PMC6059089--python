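"""OLS fits, AICc ranking, Akaike weights, collinearity and adjusted effects."""

import numpy as np
import pandas as pd
import pytest

from ectogas.modeling import (
    adjusted_effect,
    aicc,
    akaike_weights,
    candidate_table,
    collinearity_screen,
    complete_cases,
    default_candidates,
    fit_glm,
    rank_models,
    season_contrasts,
)


def _frame(n, rng, season=True):
    seasons = rng.choice(["spring", "summer", "fall"], size=n)
    return pd.DataFrame(
        {
            "season": seasons,
            "activity": rng.choice(["bright", "quiet"], size=n),
            "pcv_pct": rng.normal(25, 5, size=n),
            "ta_c": rng.normal(20, 3, size=n),
            "y": rng.standard_normal(n),
        }
    )


class TestFitGlm:
    def test_perfect_line(self):
        df = pd.DataFrame({"pcv_pct": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 3.0],
                           "season": ["spring"] * 3, "activity": ["bright"] * 3})
        fit = fit_glm(df, "y", ("pcv",))
        assert fit.params["pcv_pct"] == pytest.approx(1.0, abs=1e-10)
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-10)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_hand_least_squares(self):
        df = pd.DataFrame({"pcv_pct": [1.0, 2.0, 3.0], "y": [1.0, 2.0, 4.0],
                           "season": ["spring"] * 3, "activity": ["bright"] * 3})
        fit = fit_glm(df, "y", ("pcv",))
        assert fit.params["pcv_pct"] == pytest.approx(1.5)
        assert fit.params["const"] == pytest.approx(-2.0 / 3.0)
        assert fit.rss == pytest.approx(1.0 / 6.0)

    def test_parameter_count_convention(self, rng):
        df = _frame(96, rng)
        assert fit_glm(df, "y", ()).k == 2  # intercept + residual variance
        assert fit_glm(df, "y", ("activity",)).k == 3
        assert fit_glm(df, "y", ("season",)).k == 4
        assert fit_glm(df, "y", ("pcv", "season")).k == 5
        assert fit_glm(df, "y", ("activity", "pcv", "season")).k == 6

    def test_gaussian_loglik_closed_form(self, rng):
        df = _frame(40, rng)
        fit = fit_glm(df, "y", ("pcv",))
        n = fit.n
        expected = -n / 2.0 * (np.log(2 * np.pi) + np.log(fit.rss / n) + 1.0)
        assert fit.loglik == pytest.approx(expected, abs=1e-9)

    def test_rank_deficient_design_named(self, rng):
        df = _frame(30, rng)
        df["season"] = "spring"  # season dummies all zero -> aliased
        with pytest.raises(ValueError, match="aliased"):
            fit_glm(df, "y", ("season",))

    def test_ols_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 31))
            df = _frame(n, rng)
            terms = ("activity", "pcv", "ta")
            fit = fit_glm(df, "y", terms)
            X = np.column_stack(
                [
                    np.ones(n),
                    (df["activity"] == "quiet").astype(float),
                    df["pcv_pct"],
                    df["ta_c"],
                ]
            )
            beta = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
            assert np.allclose(fit.params.to_numpy(), beta, atol=1e-8)


class TestAicc:
    def test_correction_term_hand_value(self, rng):
        df = _frame(96, rng)
        fit = fit_glm(df, "y", ())
        aic = -2 * fit.loglik + 2 * fit.k
        assert aicc(fit) - aic == pytest.approx(12.0 / 93.0)

    def test_approaches_aic_as_n_grows(self, rng):
        gaps = []
        for n in (30, 100, 1000):
            df = _frame(n, rng)
            fit = fit_glm(df, "y", ("pcv",))
            gaps.append(aicc(fit) - (-2 * fit.loglik + 2 * fit.k))
        assert gaps[0] > gaps[1] > gaps[2] > 0

    def test_undefined_when_n_too_small(self, rng):
        df = _frame(7, rng)
        fit = fit_glm(df, "y", ("activity", "pcv", "season"))
        fit.n = fit.k + 1
        with pytest.raises(ValueError):
            aicc(fit)


class TestRanking:
    # printed ΔAICc -> printed weights, per analyte (2 dp)
    PRINTED = {
        "ph": ([0, 26.57, 54.93, 59.00, 75.24], [1.00, 0.00, 0.00, 0.00, 0.00]),
        "po2": ([0, 0.46, 5.22, 8.53, 12.38], [0.53, 0.42, 0.04, 0.01, 0.00]),
        "pco2": ([0, 32.87, 57.35, 61.49, 80.34], [1.00, 0.00, 0.00, 0.00, 0.00]),
        "hco3": ([0, 0.40, 21.54, 24.82, 27.24], [0.55, 0.45, 0.00, 0.00, 0.00]),
        "tco2": ([0, 1.62, 17.17, 20.50, 21.10], [0.69, 0.31, 0.00, 0.00, 0.00]),
        "lactate": ([0, 1.93, 7.09, 20.09, 21.56], [0.71, 0.27, 0.02, 0.00, 0.00]),
        "be": ([0, 0.53, 25.0, 34.94, 35.76], [0.57, 0.43, 0.00, 0.00, 0.00]),
    }

    @pytest.mark.parametrize("analyte", sorted(PRINTED))
    def test_weight_reproduction_from_published_deltas(self, analyte):
        deltas, expected = self.PRINTED[analyte]
        w = akaike_weights(deltas)
        assert np.allclose(w, expected, atol=0.01)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_model_weight_one(self, rng):
        df = _frame(40, rng)
        ranks = rank_models([fit_glm(df, "y", ("pcv",))])
        assert ranks[0].weight == pytest.approx(1.0) and ranks[0].delta == 0.0

    def test_rank_table_invariants(self, rng):
        df = _frame(80, rng)
        fits = [fit_glm(df, "y", c.terms) for c in default_candidates("y")]
        ranks = rank_models(fits)
        assert sum(r.delta == 0.0 for r in ranks) == 1
        assert sum(r.weight for r in ranks) == pytest.approx(1.0, abs=1e-9)
        assert [r.aicc for r in ranks] == sorted(r.aicc for r in ranks)

    def test_differing_n_rejected(self, rng):
        a = fit_glm(_frame(40, rng), "y", ("pcv",))
        b = fit_glm(_frame(41, rng), "y", ("pcv",))
        with pytest.raises(ValueError, match="case-wise"):
            rank_models([a, b])

    def test_row_permutation_invariance(self, rng):
        df = _frame(60, rng)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = candidate_table(df, "y")
        b = candidate_table(shuffled, "y")
        for ra, rb in zip(a, b):
            assert ra.model.name == rb.model.name
            assert ra.aicc == pytest.approx(rb.aicc, abs=1e-9)


class TestCandidateTable:
    def test_case_wise_deletion_shared_across_models(self, rng):
        df = _frame(60, rng)
        df.loc[:2, "activity"] = None  # 3 missing activity
        df.loc[3, "pcv_pct"] = np.nan  # 1 missing PCV
        df.loc[4, ["activity", "pcv_pct"]] = None, np.nan  # 1 missing both
        ranks = candidate_table(df, "y")
        assert all(r.n == 55 for r in ranks)

    def test_all_noise_response_prefers_null(self, rng):
        close = 0
        for _ in range(30):
            df = _frame(120, np.random.default_rng(rng.integers(2**31)))
            ranks = candidate_table(df, "y")
            null_delta = next(r.delta for r in ranks if r.model.name == "Null")
            close += null_delta <= 2.0
        assert close >= 20  # Null within 2 AICc of the top in most replicates


class TestCollinearity:
    def test_identical_columns_flagged(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [1.0, 2, 3, 4]})
        out = collinearity_screen(df, ["x", "y"])
        assert out[0]["r"] == pytest.approx(1.0) and out[0]["flagged"]

    def test_independent_pair_not_flagged(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(1000), "y": rng.standard_normal(1000)})
        out = collinearity_screen(df, ["x", "y"])
        assert abs(out[0]["r"]) < 0.1 and not out[0]["flagged"]

    def test_constant_column_warns(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning):
            out = collinearity_screen(df, ["x", "y"])
        assert np.isnan(out[0]["r"]) and not out[0]["flagged"]

    def test_pcv_vs_temperature_in_default_cohort(self, corrected_frame):
        out = collinearity_screen(corrected_frame, ["pcv_pct", "ta_c"])
        assert 0.0 < out[0]["r"] < 0.5 and not out[0]["flagged"]


class TestAdjustedEffects:
    def test_exposure_in_adjustment_set_rejected(self, rng):
        with pytest.raises(ValueError):
            adjusted_effect(_frame(50, rng), "y", "pcv", ("pcv",))

    def test_null_exposure_small_estimate(self, rng):
        ps = []
        for _ in range(40):
            df = _frame(200, np.random.default_rng(rng.integers(2**31)))
            e = adjusted_effect(df, "y", "activity", ())
            ps.append(e.p)
        # p uniform under the null: roughly 5% below 0.05, none absurdly tiny en masse
        assert 0 <= sum(p < 0.05 for p in ps) <= 8
        assert min(ps) > 1e-6

    def test_confounding_removed_by_adjustment(self, rng):
        # season confounds pcv -> y: crude slope biased, adjusted recovers truth
        n = 4000
        season = rng.choice(["spring", "summer", "fall"], size=n)
        pcv = 25 + 7.0 * (season == "summer") + 2.3 * (season == "fall") + rng.normal(0, 3, n)
        y = 1.0 * (season == "summer") + 0.0 * pcv + rng.normal(0, 1, n)
        df = pd.DataFrame(
            {"season": season, "pcv_pct": pcv, "y": y,
             "activity": "bright", "ta_c": 20.0}
        )
        crude = adjusted_effect(df, "y", "pcv", ())
        adjusted = adjusted_effect(df, "y", "pcv", ("season",))
        assert abs(crude.estimate) > 3 * abs(adjusted.estimate)
        assert adjusted.ci_low <= 0.0 <= adjusted.ci_high


class TestSeasonContrasts:
    def test_balanced_no_covariate_equals_raw_mean_differences(self, rng):
        df = _frame(90, rng)
        df["season"] = np.repeat(["spring", "summer", "fall"], 30)
        fit = fit_glm(df, "y", ("season",))
        contrasts = {c.exposure: c.estimate for c in season_contrasts(fit)}
        means = df.groupby("season")["y"].mean()
        assert contrasts["season:summer - spring"] == pytest.approx(
            means["summer"] - means["spring"], abs=1e-10
        )
        assert contrasts["season:fall - summer"] == pytest.approx(
            means["fall"] - means["summer"], abs=1e-10
        )

    def test_three_pairwise_contrasts(self, rng):
        fit = fit_glm(_frame(60, rng), "y", ("pcv", "season"))
        assert len(season_contrasts(fit)) == 3

    def test_requires_season_in_fit(self, rng):
        fit = fit_glm(_frame(60, rng), "y", ("pcv",))
        with pytest.raises(ValueError):
            season_contrasts(fit)


def test_complete_cases_counts(rng):
    df = _frame(50, rng)
    df.loc[0, "pcv_pct"] = np.nan
    cc = complete_cases(df, "y", default_candidates("y"))
    assert len(cc) == 49
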