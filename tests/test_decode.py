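"""Decoding suite: response matrices, subpopulations, classifiers, controls."""

import numpy as np
import pandas as pd
import pytest

import lamdec
from lamdec.csd import build_laminar_model
from lamdec.decode import (DecodeConfig, PopulationResponse, _FastLDA,
                           _FastNB, build_response_matrix,
                           build_subpopulations, decode_pair,
                           gaussian_nb_predict, neuron_dropping_curve,
                           pairwise_decode, sensitivity,
                           shuffle_training_trials, single_neuron_decode)

MODEL = build_laminar_model(1242.0)


def _gaussian_pair(rng, n_per_class=50, n_neurons=4, sep=0.0):
    X = rng.standard_normal((2 * n_per_class, n_neurons))
    X[n_per_class:] += sep
    y = np.repeat([0, 90], n_per_class)
    return X, y


class TestResponseMatrix:
    def test_trials_per_pair_bookkeeping(self):
        cfg = lamdec.SessionConfig(n_neurons=4, sf_set=(2.0,),
                                   reps_per_direction=10, seed=4)
        s = lamdec.generate_session(cfg)
        pop = build_response_matrix(s)
        # 10 reps x 2 directions per orientation -> 40 trials per pair
        counts = pd.Series(pop.y).value_counts()
        assert (counts == 20).all()
        a, b = np.unique(pop.y)[:2]
        assert int(((pop.y == a) | (pop.y == b)).sum()) == 40

    def test_normalization_unit_max(self, small_session):
        pop = build_response_matrix(small_session)
        assert np.allclose(pop.X.max(axis=0), 1.0)
        assert pop.X.min() >= 0.0

    def test_orientation_labels(self, small_session):
        pop = build_response_matrix(small_session)
        assert set(np.unique(pop.y)) == set(range(0, 180, 10))

    def test_window_outside_trial_rejected(self, small_session):
        with pytest.raises(ValueError):
            build_response_matrix(small_session, window=(0.05, 2.0))


class TestSubpopulations:
    def test_sliding_window_count(self, rng):
        depths = np.sort(rng.uniform(0, 1700, 30))
        subs = build_subpopulations(depths, MODEL, k=10)
        assert len(subs) == 21            # N - k + 1

    def test_single_neuron_mode(self, rng):
        depths = np.sort(rng.uniform(0, 1700, 5))
        subs = build_subpopulations(depths, MODEL, k=1)
        assert len(subs) == 5
        assert all(len(s.indices) == 1 for s in subs)

    def test_same_depth_same_compartment(self):
        depths = np.full(12, 1000.0)
        subs = build_subpopulations(depths, MODEL, k=10)
        assert {s.compartment for s in subs} == {"4C"}

    def test_even_k_center_is_mean_of_middle_pair(self):
        depths = np.arange(10, dtype=float) * 100.0
        subs = build_subpopulations(depths, MODEL, k=10)
        assert subs[0].center_depth == pytest.approx((400.0 + 500.0) / 2)

    def test_too_few_neurons_warns_empty(self):
        with pytest.warns(UserWarning):
            subs = build_subpopulations(np.arange(5.0), MODEL, k=10)
        assert subs == []


class TestClassifierBackends:
    @pytest.mark.parametrize("family", ["LogR", "LDA", "NB", "SVM", "RF"])
    def test_separable_classes_perfect(self, rng, family):
        X, y = _gaussian_pair(rng, sep=15.0)
        cfg = DecodeConfig(outer_folds=5, inner_folds=3,
                           c_grid=(0.1, 1.0, 10.0), n_trees=25, seed=0)
        assert decode_pair(X, y, family, cfg, seed=0) == 1.0

    @pytest.mark.parametrize("family", ["LogR", "LDA", "NB", "SVM", "RF"])
    def test_chance_on_unrelated_labels(self, rng, family):
        X, y = _gaussian_pair(rng, n_per_class=100, sep=0.0)
        cfg = DecodeConfig(outer_folds=5, inner_folds=3,
                           c_grid=(0.1, 1.0, 10.0), n_trees=25, seed=0)
        acc = decode_pair(X, y, family, cfg, seed=1)
        se = np.sqrt(0.25 / len(y))
        assert abs(acc - 0.5) < 4 * se + 0.05

    def test_fast_lda_matches_sklearn(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        for _ in range(20):
            X, y = _gaussian_pair(rng, n_per_class=20, sep=1.0)
            Xt = rng.standard_normal((30, X.shape[1]))
            ours = _FastLDA().fit(X, y).predict(Xt)
            ref = LinearDiscriminantAnalysis(
                solver="lsqr", shrinkage="auto").fit(X, y).predict(Xt)
            assert np.array_equal(ours, ref)

    def test_fast_nb_matches_sklearn(self, rng):
        from sklearn.naive_bayes import GaussianNB
        for _ in range(20):
            X, y = _gaussian_pair(rng, n_per_class=20, sep=1.0)
            Xt = rng.standard_normal((30, X.shape[1]))
            assert np.array_equal(_FastNB().fit(X, y).predict(Xt),
                                  GaussianNB().fit(X, y).predict(Xt))

    def test_lda_matches_closed_form_discriminant(self, rng):
        """2-neuron toy: predictions equal sign of w.(x - mid) with
        w = S^-1 (mu1 - mu0) computed by hand."""
        X, y = _gaussian_pair(rng, n_per_class=30, n_neurons=2, sep=2.0)
        clf = _FastLDA().fit(X, y)
        mu0, mu1 = X[y == 0].mean(0), X[y == 90].mean(0)
        S = _FastLDA._lw_cov(X[y == 0]) * 0.5 + _FastLDA._lw_cov(X[y == 90]) * 0.5
        w = np.linalg.solve(S, mu1 - mu0)
        Xt = rng.standard_normal((50, 2))
        expect = np.where((Xt - 0.5 * (mu0 + mu1)) @ w > 0, 90, 0)
        assert np.array_equal(clf.predict(Xt), expect)

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            decode_pair(X, np.zeros(10, dtype=int), "LDA", DecodeConfig(), 0)


class TestGaussianNbOracle:
    def test_posterior_product_brute_force(self):
        # 2-feature toy: argmax_k P(k) prod_i N(x_i; mu_ik, s_ik^2)
        means = np.array([[0.0, 1.0], [2.0, 3.0]])
        var = np.array([[1.0, 0.5], [2.0, 1.0]])
        priors = np.array([0.3, 0.7])
        rng = np.random.default_rng(0)
        X = rng.uniform(-2, 5, size=(200, 2))

        def brute(x):
            post = []
            for k in range(2):
                p = priors[k]
                for i in range(2):
                    p *= np.exp(-(x[i] - means[k, i]) ** 2 / (2 * var[k, i])) \
                        / np.sqrt(2 * np.pi * var[k, i])
                post.append(p)
            return int(np.argmax(post))

        ours = gaussian_nb_predict(X, means, var, priors)
        assert np.array_equal(ours, [brute(x) for x in X])

    def test_midpoint_tie_goes_to_class_zero(self):
        means = np.array([[-1.0], [1.0]])
        var = np.array([[1.0], [1.0]])
        assert gaussian_nb_predict([[0.0]], means, var, [0.5, 0.5])[0] == 0

    def test_uninformative_features_follow_prior(self, rng):
        means = np.zeros((2, 3))
        var = np.ones((2, 3))
        X = rng.standard_normal((50, 3))
        out = gaussian_nb_predict(X, means, var, [0.2, 0.8])
        assert (out == 1).all()


class TestShuffling:
    def test_single_trial_per_class_unchanged(self, rng):
        X = rng.random((2, 4))
        y = np.array([0, 90])
        assert np.array_equal(shuffle_training_trials(X, y, rng), X)

    def test_class_means_preserved(self, rng):
        X = rng.random((40, 6))
        y = np.repeat([0, 90], 20)
        out = shuffle_training_trials(X, y, rng)
        for label in (0, 90):
            assert np.allclose(out[y == label].mean(0), X[y == label].mean(0))
            assert np.allclose(np.sort(out[y == label], axis=0),
                               np.sort(X[y == label], axis=0))

    def test_planted_correlation_destroyed(self, rng):
        z = rng.standard_normal(1000)
        X = (np.sqrt(0.3) * z[:, None]
             + np.sqrt(0.7) * rng.standard_normal((1000, 8)))
        y = np.zeros(1000, dtype=int)
        out = shuffle_training_trials(X, y, rng)
        c = np.corrcoef(out.T)
        assert abs(c[np.triu_indices(8, 1)].mean()) < 0.02


class TestSensitivity:
    @staticmethod
    def _pair_table(acc_fn):
        oris = np.arange(0, 180, 10)
        rows = []
        for i, a in enumerate(oris):
            for b in oris[i + 1:]:
                d = min(b - a, 180 - (b - a))
                rows.append(dict(ori_a=a, ori_b=b, accuracy=acc_fn(d)))
        return pd.DataFrame(rows)

    def test_worked_interpolation(self):
        # 50% at 10 deg and 70% at 20 deg cross 60% at 15 deg
        table = self._pair_table(lambda d: 0.5 if d == 10 else 0.7)
        out = sensitivity(table)
        assert np.allclose(out["dtheta_min"], 15.0)
        assert np.allclose(out["sensitivity"], 1.0 / 15.0)

    def test_ceiling_clamps_at_10(self):
        out = sensitivity(self._pair_table(lambda d: 1.0))
        assert (out["dtheta_min"] == 10.0).all()

    def test_chance_floors_at_90(self):
        out = sensitivity(self._pair_table(lambda d: 0.5))
        assert (out["dtheta_min"] == 90.0).all()
        assert np.allclose(out["sensitivity"], 1.0 / 90.0)

    def test_missing_grid_rejected(self):
        with pytest.raises(ValueError):
            sensitivity(pd.DataFrame({"ori_a": [0], "ori_b": [10],
                                      "accuracy": [0.9]}))


class TestNeuronDropping:
    def _pop(self, rng, n_neurons=5):
        n = 40
        y = np.repeat(np.arange(0, 40, 10), n // 4)
        X = (y[:, None] / 40.0
             + 0.3 * rng.standard_normal((n, n_neurons)))
        X = X - X.min(axis=0)
        X = X / X.max(axis=0)
        return PopulationResponse(X, y, np.arange(n_neurons, dtype=float),
                                  np.arange(n_neurons), np.arange(n))

    def test_full_size_single_combination(self, rng):
        pop = self._pop(rng)
        out = neuron_dropping_curve(pop, [5], DecodeConfig(outer_folds=5),
                                    reps=200, rng=rng)
        assert out["combination"].nunique() == 1

    def test_all_combinations_when_few(self, rng):
        pop = self._pop(rng)
        out = neuron_dropping_curve(pop, [2], DecodeConfig(outer_folds=5),
                                    reps=200, rng=rng)
        assert out["combination"].nunique() == 10   # C(5, 2)

    def test_rep_cap(self, rng):
        pop = self._pop(rng, n_neurons=8)
        out = neuron_dropping_curve(pop, [3], DecodeConfig(outer_folds=5),
                                    reps=7, rng=rng)
        assert out["combination"].nunique() == 7


def test_pair_enumeration_and_seeding(small_session):
    """18 orientations give exactly 153 binary problems, reproducibly."""
    pop = build_response_matrix(small_session)
    cfg = DecodeConfig(outer_folds=5, seed=42)
    sub = pop.subset(range(10))
    a = pairwise_decode(sub, "LDA", cfg)
    b = pairwise_decode(sub, "LDA", cfg)
    assert len(a) == 153
    assert a.equals(b)


def test_pair_distance_restriction(small_session):
    """max_dtheta keeps only pairs within the angular distance: 18
    orientations have 36 pairs at 10-20 deg separation."""
    pop = build_response_matrix(small_session)
    out = pairwise_decode(pop.subset(range(4)), "NB",
                          DecodeConfig(outer_folds=2, seed=0), max_dtheta=20)
    assert len(out) == 36
    d = np.minimum(out.ori_b - out.ori_a, 180 - (out.ori_b - out.ori_a))
    assert d.max() <= 20


def test_single_neuron_weaker_than_population(small_session, small_model):
    """Information monotonicity: 10-neuron subpopulations beat their
    constituent single neurons on average."""
    pop = build_response_matrix(small_session)
    cfg = DecodeConfig(outer_folds=5, seed=0)
    subs = build_subpopulations(pop.depths, small_model, k=10, stride=10)
    pop_acc = lamdec.decode_subpopulations(pop, subs, cfg, families=("LDA",))
    single = single_neuron_decode(pop.subset(subs[0].indices), small_model,
                                  cfg, families=("LDA",))
    assert single["accuracy"].mean() < pop_acc["accuracy"].mean()
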