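"""Standardization, EM fitting, posteriors and candidate calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from nmpredict import (
    AmbiguousModelError,
    DegenerateInputError,
    InvalidInputError,
    MixtureModel,
    Standardization,
    call_nm_candidates,
    em_fit,
    identify_low_gc_component,
    posterior,
    standardize,
)


def two_cluster_data(rng, n_per=1000, mu=2.0):
    X = np.vstack([
        rng.normal(-mu, 1.0, size=(n_per, 3)),
        rng.normal(+mu, 1.0, size=(n_per, 3)),
    ])
    labels = np.repeat([0, 1], n_per)
    return X, labels


class TestStandardize:
    def test_two_point_column_z_scores_to_plus_minus_one(self):
        Xs, std = standardize(np.array([[1.0, 1.0, 0.0], [3.0, 5.0, 2.0]]))
        assert Xs[:, 0] == pytest.approx([-1.0, 1.0])
        assert std.sd == pytest.approx([1.0, 2.0, 1.0])  # population sd, denominator n

    def test_already_standard_sample_is_near_identity(self, rng):
        X = rng.standard_normal((5000, 3))
        Xs, std = standardize(X)
        assert std.mean == pytest.approx(np.zeros(3), abs=0.05)
        assert std.sd == pytest.approx(np.ones(3), abs=0.05)

    def test_columns_have_zero_mean_unit_sd(self, rng):
        X = rng.uniform(-5, 9, size=(200, 3))
        Xs, std = standardize(X)
        assert Xs.mean(axis=0) == pytest.approx(np.zeros(3), abs=1e-10)
        assert Xs.std(axis=0) == pytest.approx(np.ones(3), abs=1e-10)
        assert std.inverse(Xs) == pytest.approx(X)

    def test_constant_feature_named_in_error(self):
        X = np.array([[0.1, 0.5, 1.0], [0.2, 0.5, 2.0], [0.3, 0.5, 3.0]])
        with pytest.raises(DegenerateInputError, match="gc3"):
            standardize(X)

    def test_matches_direct_zscore_oracle(self, rng):
        X = rng.normal(3, 7, size=(80, 3))
        Xs, _ = standardize(X)
        assert Xs == pytest.approx((X - X.mean(0)) / X.std(0))


class TestEmFit:
    def test_recovers_well_separated_clusters(self, rng):
        X, _ = two_cluster_data(rng)
        Xs, std = standardize(X)
        model = em_fit(Xs, seed=3)
        means = std.inverse(model.means)
        order = np.argsort(means[:, 0])
        assert means[order[0]] == pytest.approx(np.full(3, -2.0), abs=0.15)
        assert means[order[1]] == pytest.approx(np.full(3, 2.0), abs=0.15)
        assert model.weights == pytest.approx([0.5, 0.5], abs=0.03)
        assert model.converged

    def test_single_gaussian_total_covariance_matches_sample(self, rng):
        """Degenerate separation: the mixture's total covariance (tied matrix
        plus between-component scatter) reproduces the sample covariance — an
        exact moment-matching identity of the M-step."""
        X = rng.multivariate_normal(np.zeros(3), np.eye(3), size=1500)
        Xs, _ = standardize(X)
        model = em_fit(Xs, seed=5)
        pooled = np.cov(Xs, rowvar=False, bias=True)
        mixture_mean = model.weights @ model.means
        assert mixture_mean == pytest.approx(Xs.mean(axis=0), abs=1e-6)
        between = sum(
            w * np.outer(mu - mixture_mean, mu - mixture_mean)
            for w, mu in zip(model.weights, model.means)
        )
        total = model.covariance + between
        assert total == pytest.approx(pooled, abs=1e-4)

    def test_log_likelihood_non_decreasing(self, rng):
        X, _ = two_cluster_data(rng, n_per=300)
        Xs, _ = standardize(X)
        for seed in range(5):
            model = em_fit(Xs, seed=seed, n_init=1)
            diffs = np.diff(model.log_likelihood_history)
            assert np.all(diffs >= -1e-8)

    def test_non_finite_input_rejected(self):
        X = np.zeros((10, 3))
        X[0, 0] = np.nan
        with pytest.raises(InvalidInputError):
            em_fit(X, seed=0)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            em_fit(np.zeros((2, 3)), seed=0)

    def test_matches_reference_em_log_likelihood(self, rng):
        """Independent cross-check: same data, same model family, same optimum."""
        sklearn = pytest.importorskip("sklearn.mixture")
        X, _ = two_cluster_data(rng, n_per=500)
        Xs, _ = standardize(X)
        ours = em_fit(Xs, seed=2, n_init=5, tol=1e-8)
        ref = sklearn.GaussianMixture(
            n_components=2, covariance_type="tied", n_init=5, tol=1e-8,
            reg_covar=1e-6, random_state=2,
        ).fit(Xs)
        assert ours.log_likelihood / len(Xs) == pytest.approx(ref.lower_bound_, abs=1e-4)


class TestPosterior:
    def test_equidistant_point_splits_evenly(self):
        model = MixtureModel(
            weights=np.array([0.5, 0.5]),
            means=np.array([[-1.0, 0, 0], [1.0, 0, 0]]),
            covariance=np.eye(3),
            log_likelihood=0.0, n_iter=1, converged=True,
        )
        assert posterior(model, np.zeros((1, 3)))[0] == pytest.approx([0.5, 0.5])

    def test_point_at_a_distant_component_mean_is_certain(self):
        model = MixtureModel(
            weights=np.array([0.5, 0.5]),
            means=np.array([[-8.0, -8, -8], [8.0, 8, 8]]),
            covariance=np.eye(3),
            log_likelihood=0.0, n_iter=1, converged=True,
        )
        assert posterior(model, model.means[[0]])[0, 0] > 0.999

    def test_matches_scipy_density_ratio_oracle(self, rng):
        for _ in range(20):
            A = rng.normal(size=(3, 3))
            cov = A @ A.T + 0.5 * np.eye(3)
            w = rng.dirichlet(np.ones(2))
            means = rng.normal(size=(2, 3))
            model = MixtureModel(weights=w, means=means, covariance=cov,
                                 log_likelihood=0.0, n_iter=1, converged=True)
            X = rng.normal(size=(15, 3))
            dens = np.column_stack([
                w[j] * multivariate_normal.pdf(X, means[j], cov) for j in range(2)
            ])
            expect = dens / dens.sum(axis=1, keepdims=True)
            assert posterior(model, X) == pytest.approx(expect, rel=1e-8)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        model = MixtureModel(
            weights=rng.dirichlet(np.ones(2)),
            means=rng.normal(size=(2, 3)),
            covariance=np.eye(3) * float(rng.uniform(0.1, 5)),
            log_likelihood=0.0, n_iter=1, converged=True,
        )
        p = posterior(model, rng.normal(size=(30, 3)))
        assert p.sum(axis=1) == pytest.approx(np.ones(30), abs=1e-12)


class TestComponentIdentification:
    std = Standardization(mean=np.array([0.45, 0.40, 2.0]), sd=np.array([0.1, 0.15, 1.0]))

    def _model(self, means):
        return MixtureModel(weights=np.array([0.5, 0.5]), means=np.asarray(means, float),
                            covariance=np.eye(3), log_likelihood=0.0, n_iter=1, converged=True)

    def test_lower_destandardized_gc3_mean_wins(self):
        # de-standardized GC3 means: 0.40 + {-0.667, +1.0} * 0.15 -> 0.30 vs 0.55
        model = self._model([[0.0, -0.667, 0.5], [0.0, 1.0, -0.5]])
        assert identify_low_gc_component(model, self.std) == 0

    def test_label_switching_invariance(self):
        model = self._model([[0.0, 1.0, -0.5], [0.0, -0.667, 0.5]])
        assert identify_low_gc_component(model, self.std) == 1

    def test_gc3_tie_breaks_on_gc1(self):
        model = self._model([[1.0, 0.3, 0.0], [-1.0, 0.3, 0.0]])
        assert identify_low_gc_component(model, self.std) == 1

    def test_exact_tie_on_both_is_ambiguous(self):
        model = self._model([[0.2, 0.3, 1.0], [0.2, 0.3, -1.0]])
        with pytest.raises(AmbiguousModelError):
            identify_low_gc_component(model, self.std)

    def test_selects_generatively_low_gc_population_across_seeds(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            low = np.column_stack([rng.normal(0.35, 0.05, 400), rng.normal(0.25, 0.05, 400),
                                   rng.normal(4.0, 1.0, 400)])
            high = np.column_stack([rng.normal(0.55, 0.05, 400), rng.normal(0.55, 0.05, 400),
                                    rng.normal(2.0, 1.0, 400)])
            Xs, std = standardize(np.vstack([low, high]))
            model = em_fit(Xs, seed=seed)
            low_idx = identify_low_gc_component(model, std)
            post = posterior(model, Xs)
            # the low-GC component must own the generatively low-GC half
            assert post[:400, low_idx].mean() > 0.9
            assert post[400:, low_idx].mean() < 0.1


class TestCandidateCalls:
    def test_strictly_over_threshold_semantics(self):
        post = np.array([[0.96, 0.04], [0.95, 0.05], [0.50, 0.50], [0.9500000001, 0.05]])
        calls = call_nm_candidates(post, 0, ["a", "b", "c", "d"])
        assert [c.is_nm_candidate for c in calls] == [True, False, False, True]

    def test_threshold_outside_open_interval_rejected(self):
        with pytest.raises(InvalidInputError):
            call_nm_candidates(np.array([[0.9, 0.1]]), 0, ["a"], threshold=0.5)

    def test_label_switching_leaves_calls_unchanged(self, rng):
        post = rng.dirichlet(np.ones(2), size=50)
        direct = call_nm_candidates(post, 0, [f"t{i}" for i in range(50)])
        swapped = call_nm_candidates(post[:, ::-1], 1, [f"t{i}" for i in range(50)])
        assert direct == swapped


def test_model_json_roundtrip(tmp_path, rng):
    X, _ = two_cluster_data(rng, n_per=200)
    Xs, std = standardize(X)
    model = em_fit(Xs, seed=1, n_init=2)
    path = tmp_path / "model.json"
    model.save(path, std)
    import json

    loaded, loaded_std = MixtureModel.from_dict(json.loads(path.read_text()))
    assert loaded.weights == pytest.approx(model.weights)
    assert loaded.means == pytest.approx(model.means)
    assert loaded_std.mean == pytest.approx(std.mean)
    assert posterior(loaded, Xs) == pytest.approx(posterior(model, Xs))
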