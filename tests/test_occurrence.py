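import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special

import wolfreports as wr
from wolfreports.occurrence import (
    ModelSpec,
    OccurrenceModel,
    build_model_matrix,
    encode_season,
    lrt,
    lrt_ladder,
    ordinal_contrasts,
)


class TestEncodeSeason:
    def test_full_circle_identity(self):
        s, c = encode_season(365)
        assert s == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(1.0, abs=1e-12)

    def test_day_one_matches_direct_trigonometry(self):
        s, c = encode_season(1)
        assert s == pytest.approx(np.sin(2 * np.pi / 365), abs=1e-15)
        assert c == pytest.approx(np.cos(2 * np.pi / 365), abs=1e-15)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 365))
    def test_unit_circle(self, J):
        s, c = encode_season(J)
        assert s**2 + c**2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [0, 366, -3])
    def test_out_of_range_raises(self, bad):
        with pytest.raises(ValueError):
            encode_season(bad)


class TestOrdinalContrasts:
    def test_linear_column_for_five_levels(self):
        """Gram-Schmidt-on-Vandermonde oracle: the degree-1 contrast is
        (-2,-1,0,1,2) normalized to unit length."""
        C = ordinal_contrasts(5)
        expected = np.array([-2, -1, 0, 1, 2]) / np.sqrt(10)
        np.testing.assert_allclose(C[:, 0], expected, atol=1e-12)

    def test_matches_r_contr_poly_for_five_levels(self):
        # quadratic column of R's contr.poly(5): (2,-1,-2,-1,2)/sqrt(14)
        C = ordinal_contrasts(5)
        np.testing.assert_allclose(
            C[:, 1], np.array([2, -1, -2, -1, 2]) / np.sqrt(14), atol=1e-12
        )

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 8])
    def test_orthonormal_zero_sum(self, n):
        C = ordinal_contrasts(n)
        assert C.shape == (n, n - 1)
        np.testing.assert_allclose(C.T @ C, np.eye(n - 1), atol=1e-10)
        np.testing.assert_allclose(C.sum(axis=0), 0.0, atol=1e-10)

    def test_unequal_scores_change_the_basis(self):
        C_rank = ordinal_contrasts(5)
        C_year = ordinal_contrasts(5, scores=(1972, 1996, 2005, 2016, 2021))
        assert not np.allclose(C_rank[:, 0], C_year[:, 0])
        np.testing.assert_allclose(C_year.T @ C_year, np.eye(4), atol=1e-10)

    def test_too_few_levels_raises(self):
        with pytest.raises(ValueError):
            ordinal_contrasts(1)


def tiny_design(n=10, seed=0):
    rng = np.random.default_rng(seed)
    J = rng.integers(1, 366, n)
    sin_t, cos_t = encode_season(J)
    return pd.DataFrame(
        {
            "case": rng.permutation([1] * (n // 2) + [0] * (n - n // 2)),
            "J": J,
            "sin_t": sin_t,
            "cos_t": cos_t,
            "S": rng.integers(1, 6, n),
            "H_z": rng.normal(size=n),
        }
    )


class TestFitOccurrence:
    def test_intercept_only_fits_case_fraction(self, design):
        spec = ModelSpec(season=False, recolonization=False, footprint=False, footprint_sq=False)
        res = OccurrenceModel(design, spec).fit()
        frac = design.df["case"].mean()
        np.testing.assert_allclose(res.fitted, frac, rtol=1e-6)

    def test_matches_bruteforce_newton_on_ten_rows(self):
        """Independent-optimizer oracle: BFGS on the explicit Bernoulli
        log-likelihood agrees with the IRLS fit to 1e-6."""
        df = tiny_design(10, seed=1)
        spec = ModelSpec(recolonization=False, footprint_sq=False)
        model = OccurrenceModel(df, spec)
        res = model.fit()
        X, y = model.X, model.y

        def nll(beta):
            eta = X @ beta
            return -(y @ eta - np.logaddexp(0, eta).sum())

        opt = optimize.minimize(nll, np.zeros(X.shape[1]), method="BFGS", tol=1e-12)
        np.testing.assert_allclose(res.params.to_numpy(), opt.x, atol=1e-6)
        assert res.llf == pytest.approx(-opt.fun, abs=1e-8)

    def test_matches_statsmodels_glm(self, design):
        import statsmodels.api as sm

        model = OccurrenceModel(design, ModelSpec())
        res = model.fit()
        ref = sm.GLM(model.y, model.X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(res.params.to_numpy(), ref.params, rtol=1e-6)
        np.testing.assert_allclose(res.bse.to_numpy(), ref.bse, rtol=1e-4)
        assert res.llf == pytest.approx(ref.llf, rel=1e-8)

    def test_empty_or_single_class_raises(self, design):
        with pytest.raises(ValueError):
            OccurrenceModel(design.df.iloc[:0], ModelSpec())
        ones = design.df[design.df["case"] == 1]
        with pytest.raises(ValueError):
            OccurrenceModel(ones, ModelSpec())

    def test_separation_is_detected(self):
        df = tiny_design(40, seed=2)
        df["H_z"] = np.where(df["case"] == 1, 1.0, -1.0) + 0.01 * np.arange(40)
        spec = ModelSpec(season=False, recolonization=False, footprint_sq=False)
        with pytest.warns(UserWarning, match="separation"):
            res = OccurrenceModel(df, spec).fit()
        assert res.separation

    def test_random_intercepts_shrink_group_effects(self, design):
        sub_ids = design.df.loc[design.df["case"] == 1, "report_id"].iloc[:80]
        d = design.subset(sub_ids)
        spec = ModelSpec(random_intercepts=("province",))
        res = OccurrenceModel(d, spec).fit()
        assert res.converged
        assert res.df_model == 9  # fixed-effect count unchanged by random terms
        assert len(res.random_sd) == 1


class TestLRT:
    def test_model_against_itself_is_null(self, design):
        res = OccurrenceModel(design, ModelSpec()).fit()
        t = lrt(res, res)
        assert t.chi2 == pytest.approx(0.0, abs=1e-8)
        assert t.df == 0 and t.pvalue == 1.0

    def test_full_vs_null_df_is_eight(self, design):
        full = OccurrenceModel(design, ModelSpec()).fit()
        null = OccurrenceModel(
            design, ModelSpec(season=False, recolonization=False, footprint=False, footprint_sq=False)
        ).fit()
        t = lrt(full, null)
        assert t.df == 8
        assert t.chi2 >= 0

    def test_reduced_model_never_beats_full(self, design):
        full = OccurrenceModel(design, ModelSpec()).fit()
        red = OccurrenceModel(design, ModelSpec(footprint_sq=False)).fit()
        assert red.llf <= full.llf + 1e-8

    def test_chi2_invariant_to_covariate_rescaling(self, design):
        full = OccurrenceModel(design, ModelSpec()).fit()
        red = OccurrenceModel(design, ModelSpec(season=False)).fit()
        df2 = design.df.copy()
        df2["H_z"] = 3.0 * df2["H_z"] - 1.0
        full2 = OccurrenceModel(df2, ModelSpec(footprint_sq=False)).fit()
        red2 = OccurrenceModel(df2, ModelSpec(season=False, footprint_sq=False)).fit()
        # compare the same nested pair before/after affine rescaling of H_z
        full1 = OccurrenceModel(design.df, ModelSpec(footprint_sq=False)).fit()
        red1 = OccurrenceModel(design.df, ModelSpec(season=False, footprint_sq=False)).fit()
        t1, t2 = lrt(full1, red1), lrt(full2, red2)
        assert t1.chi2 == pytest.approx(t2.chi2, rel=1e-5)

    def test_non_nested_raises(self, design):
        a = OccurrenceModel(design, ModelSpec(season=False)).fit()
        b = OccurrenceModel(design, ModelSpec(footprint=False, footprint_sq=False)).fit()
        with pytest.raises(ValueError, match="nested"):
            lrt(a, b)


class TestLRTLadder:
    def test_df_column(self, design):
        lad = lrt_ladder(design)
        assert list(lad["factor"]) == ["season", "recolonization", "footprint", "footprint_sq"]
        assert list(lad["df"]) == [2, 4, 2, 1]
        assert (lad["chi2"] >= 0).all()


class TestDispersion:
    def test_well_specified_fit_near_one(self, design):
        res = OccurrenceModel(design, ModelSpec()).fit()
        assert 0.9 <= res.dispersion() <= 1.1

    def test_matches_bruteforce_residuals(self):
        df = tiny_design(10, seed=3)
        spec = ModelSpec(season=False, recolonization=False, footprint_sq=False)
        model = OccurrenceModel(df, spec)
        res = model.fit()
        mu = res.fitted
        brute = sum(
            (y - m) ** 2 / (m * (1 - m)) for y, m in zip(model.y, mu)
        ) / (10 - res.df_model)
        assert res.dispersion() == pytest.approx(brute, rel=1e-10)
        assert res.dispersion() >= 0


class TestPredictCurve:
    def test_scores_increase_with_linear_predictor(self, design):
        res = OccurrenceModel(design, ModelSpec()).fit()
        curve = res.predict_curve("footprint")
        order = np.argsort(curve["eta"].to_numpy())
        assert (np.diff(curve["score"].to_numpy()[order]) >= -1e-12).all()

    def test_seasonal_peak_recovered(self, land, truth):
        reps = wr.simulate_reports(land, truth, 2000, seed=41)
        reps = wr.assign_reporters(reps, seed=42)
        d = wr.build_design(reps, land, ratio=11, seed=43)
        res = OccurrenceModel(d, ModelSpec()).fit()
        curve = res.predict_curve("season")
        est = curve.loc[curve["score"].idxmax(), "grid"]
        diff = abs(est - truth.seasonal_peak_day)
        assert min(diff, 365 - diff) <= 15

    def test_footprint_argmax_recovered(self, land):
        """A quadratic footprint truth with an interior maximum is recovered
        with argmax within 10% of the true peak."""
        truth = wr.GenerativeTruth(gamma=np.zeros(5), beta_H=0.28, beta_H2=-0.004)
        true_peak = -truth.beta_H / (2 * truth.beta_H2)
        reps = wr.simulate_reports(land, truth, 3000, seed=44)
        reps = wr.assign_reporters(reps, seed=45)
        d = wr.build_design(reps, land, ratio=11, seed=46)
        res = OccurrenceModel(d, ModelSpec(recolonization=False)).fit()
        curve = res.predict_curve("footprint", grid=np.linspace(5, 50, 300))
        est_peak = curve.loc[curve["score"].idxmax(), "grid"]
        assert abs(est_peak - true_peak) <= 0.1 * true_peak

    def test_extrapolation_warns(self, design):
        res = OccurrenceModel(design, ModelSpec()).fit()
        with pytest.warns(UserWarning, match="training range"):
            res.predict_curve("footprint", grid=np.array([0.0, 80.0]))


def test_summary_mentions_terms(design):
    res = OccurrenceModel(design, ModelSpec()).fit()
    text = res.summary()
    for term in ("sin_t", "S_lin", "H_z2"):
        assert term in text
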