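import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import wolfreports as wr
from wolfreports.valence import ValenceModel, _eval_basis, auc, build_spline_basis
from conftest import make_valence_frame


class TestSplineBasis:
    @pytest.fixture(scope="class")
    def xs(self):
        return np.random.default_rng(0).uniform(-2, 2, 400)

    def test_partition_of_unity(self, xs):
        B, _, _ = build_spline_basis(xs, k=25)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-10)

    def test_linear_coefficient_vector_in_penalty_null_space(self, xs):
        # second differences annihilate coefficient vectors linear in index
        B, P, t = build_spline_basis(xs, k=10, penalty_order=2)
        coef = 2.0 * np.arange(10) + 1.0
        assert coef @ P @ coef == pytest.approx(0.0, abs=1e-10)

    def test_matches_de_boor_recursion(self, xs):
        """Direct-recursion oracle: Cox-de Boor evaluation of every basis
        function agrees with the scipy design matrix."""
        B, _, t = build_spline_basis(xs[:50], k=8)

        def de_boor(i, k, x):
            if k == 0:
                # half-open spans; the last span is closed at the right edge
                if t[i] <= x < t[i + 1]:
                    return 1.0
                if x == t[-1] and t[i] < t[i + 1] <= t[-1] and t[i + 1] == t[-1]:
                    return 1.0
                return 0.0
            left = 0.0 if t[i + k] == t[i] else (x - t[i]) / (t[i + k] - t[i]) * de_boor(i, k - 1, x)
            right = (
                0.0
                if t[i + k + 1] == t[i + 1]
                else (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * de_boor(i + 1, k - 1, x)
            )
            return left + right

        brute = np.array([[de_boor(i, 3, x) for i in range(8)] for x in xs[:50]])
        np.testing.assert_allclose(B, brute, atol=1e-10)

    def test_k_exceeding_distinct_values_raises(self):
        with pytest.raises(ValueError):
            build_spline_basis(np.array([0.0, 1.0, 2.0] * 10), k=5)

    def test_prediction_clips_to_training_range(self, xs):
        _, _, t = build_spline_basis(xs, k=10)
        B_out = _eval_basis(np.array([xs.min() - 5, xs.max() + 5]), t)
        np.testing.assert_allclose(B_out.sum(axis=1), 1.0, atol=1e-10)


class TestAUC:
    def test_perfect_separation(self):
        assert auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_scores_equal(self):
        assert auc([5.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_eight_point_example_matches_pair_enumeration(self):
        scores = np.array([0.2, 0.8, 0.4, 0.4, 0.9, 0.1, 0.6, 0.4])
        labels = np.array([0, 1, 0, 1, 1, 0, 0, 1])
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        brute = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
        assert auc(scores, labels) == pytest.approx(brute, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc([1, 2, 3], [1, 1, 1])

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_and_antisymmetric(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=30)
        labels = np.r_[np.ones(10), np.zeros(20)].astype(int)
        a = auc(scores, labels)
        assert 0.0 <= a <= 1.0
        assert auc(-scores, labels) == pytest.approx(1.0 - a)


class TestFitValence:
    def test_null_data_gives_flat_curve(self, land, truth):
        flat = wr.GenerativeTruth(
            valence_shape=np.zeros(101), valence_zone=np.zeros(5), neutral_frac=0.0
        )
        data = make_valence_frame(land, flat, 2000, seed=50)
        res = ValenceModel(data, wr.SplineSpec()).fit()
        grid = np.linspace(data["H_z"].min(), data["H_z"].max(), 100)
        f = res.smooth_curve(grid)
        p = expit(f - f.mean() + np.log(data["negative"].mean() / (1 - data["negative"].mean())))
        assert p.max() - p.min() < 0.1

    def test_plateau_truth_recovered(self, land, truth):
        data = make_valence_frame(land, truth, 2000, seed=52)
        res = ValenceModel(data, wr.SplineSpec()).fit()
        m, s = data.attrs["h_scale"]
        # compare on the footprint range the data actually covers
        H_obs = m + s * data["H_z"]
        grid_H = np.linspace(H_obs.quantile(0.01), H_obs.quantile(0.99), 100)
        fhat = res.smooth_curve((grid_H - m) / s)
        assert wr.spearman(fhat, truth.g(grid_H)) >= 0.9

    def test_aic_prefers_simpler_fit_for_linear_truth(self, land, truth):
        """Model-selection check: a linear-in-H truth needs fewer effective
        df than the rise-then-plateau truth, in most replicates."""
        wins = 0
        n_rep = 10
        for rep in range(n_rep):
            lin = wr.GenerativeTruth(
                valence_grid=np.linspace(0, 50, 101),
                valence_shape=np.linspace(-0.8, 0.8, 101),
                valence_zone=np.zeros(5),
                neutral_frac=0.0,
            )
            d_lin = make_valence_frame(land, lin, 800, seed=60 + rep)
            d_pla = make_valence_frame(land, truth, 800, seed=60 + rep)
            edf_lin = ValenceModel(d_lin, wr.SplineSpec()).fit().edf
            edf_pla = ValenceModel(d_pla, wr.SplineSpec()).fit().edf
            # ties at the penalty-null-space floor count as "not more complex"
            wins += edf_lin <= edf_pla + 0.05
        assert wins > n_rep / 2

    def test_single_class_raises(self, valence_data):
        bad = valence_data.assign(negative=1)
        with pytest.raises(ValueError):
            ValenceModel(bad, wr.SplineSpec())

    def test_chosen_penalty_minimizes_aic_on_grid(self, valence_data):
        res = ValenceModel(valence_data, wr.SplineSpec()).fit()
        assert res.aic <= res.aic_path["aic"].min() + 1e-9

    def test_effective_df_monotone_in_penalty(self, valence_data):
        res = ValenceModel(valence_data, wr.SplineSpec()).fit()
        path = res.aic_path.copy()
        path["lam"] = path["lambda"].apply(lambda t: t[0])
        path = path.sort_values("lam")
        assert (np.diff(path["edf"].to_numpy()) <= 1e-8).all()

    def test_spatial_smoother_fits(self, valence_data):
        spec = wr.SplineSpec(
            include_spatial=True, k_spatial=20, smoothing_grid=np.logspace(0, 3, 3)
        )
        res = ValenceModel(valence_data, spec).fit()
        assert res.converged
        assert res.edf <= 25 + 4 + 20

    def test_fitted_probabilities_in_unit_interval(self, valence_data):
        res = ValenceModel(valence_data, wr.SplineSpec()).fit()
        assert ((res.fitted > 0) & (res.fitted < 1)).all()


class TestRepeatedSplitAUC:
    def test_null_labels_give_chance_auc(self, land):
        flat = wr.GenerativeTruth(
            valence_shape=np.zeros(101), valence_zone=np.zeros(5), neutral_frac=0.0
        )
        data = make_valence_frame(land, flat, 1000, seed=70)
        mean, sd, vals = wr.repeated_split_auc(data, wr.SplineSpec(), n_rep=30, seed=71)
        assert 0.45 <= mean <= 0.55

    def test_strong_signal_gives_high_auc(self, land):
        strong = wr.GenerativeTruth(
            valence_shape=-6.0 + 12.0 * expit((np.linspace(0, 50, 101) - 25) / 4),
            valence_zone=np.zeros(5),
            neutral_frac=0.0,
        )
        data = make_valence_frame(land, strong, 1000, seed=72)
        mean, _, _ = wr.repeated_split_auc(data, wr.SplineSpec(), n_rep=15, seed=73)
        assert mean > 0.9

    def test_identical_seed_identical_result(self, valence_data):
        a = wr.repeated_split_auc(valence_data, wr.SplineSpec(), n_rep=5, seed=74)
        b = wr.repeated_split_auc(valence_data, wr.SplineSpec(), n_rep=5, seed=74)
        assert a[0] == b[0] and a[1] == b[1]

    def test_invalid_parameters_raise(self, valence_data):
        with pytest.raises(ValueError):
            wr.repeated_split_auc(valence_data, n_rep=0)
        with pytest.raises(ValueError):
            wr.repeated_split_auc(valence_data, train_frac=1.2)
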