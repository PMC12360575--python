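import numpy as np
import pytest
from scipy.stats import norm

import pcmrisk as pm
from pcmrisk.bayes_error import (
    bhattacharyya_bounds,
    bounds_report,
    knn_bounds,
    mahalanobis_bound,
)
from pcmrisk.exceptions import TooFewSamples
from pcmrisk.simulate import GeneratorConfig

from oracles import bayes_error_gaussian_1d


def gaussian_sample(n, mu0, mu1, seed, s0=1.0, s1=1.0):
    rng = np.random.default_rng(seed)
    X = np.r_[rng.normal(mu0, s0, n // 2), rng.normal(mu1, s1, n - n // 2)]
    y = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
    return X[:, None], y


class TestMahalanobis:
    def test_equal_means_limit(self):
        X, y = gaussian_sample(40_000, 0.0, 0.0, seed=0)
        est = mahalanobis_bound(X, y)
        assert est.E_low is None
        assert est.E_up == pytest.approx(0.5, abs=0.01)

    def test_closed_form_separation_four(self):
        # means 0 and 4, unit variance, equal priors: Delta=16, E_up=0.1
        X, y = gaussian_sample(50_000, 0.0, 4.0, seed=1)
        est = mahalanobis_bound(X, y)
        assert est.E_up == pytest.approx(0.1, abs=0.01)

    def test_monotone_decreasing_in_separation(self):
        ups = [mahalanobis_bound(*gaussian_sample(20_000, 0.0, d, seed=2)).E_up
               for d in (0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(ups, ups[1:]))

    def test_singular_covariance_reported_as_status(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        X = np.c_[x, x]   # duplicated column: rank deficient
        y = (rng.random(200) < 0.5).astype(int)
        est = mahalanobis_bound(X, y)
        assert est.status == "singular_covariance"
        assert est.E_up is None


class TestBhattacharyya:
    def test_identical_distributions_give_half(self):
        X, y = gaussian_sample(50_000, 0.0, 0.0, seed=3)
        est = bhattacharyya_bounds(X, y)
        assert est.E_up == pytest.approx(0.5, abs=0.01)
        assert est.E_low == pytest.approx(0.5, abs=0.01)

    def test_closed_form_unit_separation_two(self):
        # N(0,1) vs N(2,1): B=0.5, E_up ~ 0.3033, E_low ~ 0.1024, and the
        # interval brackets the true Bayes error Phi(-1) ~ 0.1587
        X, y = gaussian_sample(50_000, 0.0, 2.0, seed=4)
        est = bhattacharyya_bounds(X, y)
        assert est.E_up == pytest.approx(0.5 * np.exp(-0.5), abs=0.01)
        assert est.E_low == pytest.approx(
            0.5 * (1 - np.sqrt(1 - np.exp(-1))), abs=0.01)
        truth = bayes_error_gaussian_1d(0.0, 1.0, 2.0, 1.0)
        assert truth == pytest.approx(norm.cdf(-1), abs=1e-6)
        assert est.E_low <= truth <= est.E_up

    def test_one_hot_block_is_singular(self):
        rng = np.random.default_rng(1)
        z = rng.integers(0, 3, size=500)
        X = np.zeros((500, 3))
        X[np.arange(500), z] = 1.0   # rows sum to 1: rank deficient
        y = (rng.random(500) < 0.5).astype(int)
        est = bhattacharyya_bounds(X, y)
        assert est.status == "singular_covariance"


class TestKnn:
    def test_separated_clusters_near_zero(self):
        X, y = gaussian_sample(2_000, -10.0, 10.0, seed=5)
        est = knn_bounds(X, y, seed=0)
        assert est.E_up < 0.01
        assert est.E_low < 0.01

    def test_uninformative_features_near_half(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(5_000, 2))
        y = (rng.random(5_000) < 0.5).astype(int)
        est = knn_bounds(X, y, seed=0)
        assert est.E_up == pytest.approx(0.5, abs=0.02)

    def test_interval_brackets_gaussian_truth(self):
        truth = bayes_error_gaussian_1d(0.0, 1.0, 2.0, 1.0)
        hits = 0
        for seed in range(10):
            X, y = gaussian_sample(5_000, 0.0, 2.0, seed=seed)
            est = knn_bounds(X, y, k=5, folds=5, seed=seed)
            hits += est.E_low <= truth <= est.E_up
        assert hits >= 6   # majority over seeds

    def test_too_few_samples(self):
        X, y = gaussian_sample(60, 0.0, 1.0, seed=0)
        with pytest.raises(TooFewSamples):
            knn_bounds(X, y, k=5)

    def test_bias_shrinks_with_sample_size(self):
        # k-NN upper bound tightens toward the truth as n grows
        truth = bayes_error_gaussian_1d(0.0, 1.0, 2.0, 1.0)
        med = []
        for n in (500, 2_000, 8_000):
            ups = [knn_bounds(*gaussian_sample(n, 0.0, 2.0, seed=s),
                              seed=s).E_up for s in range(5)]
            med.append(np.median(ups) - truth)
        assert med[0] > med[2]


class TestBounds:
    def test_bounds_well_ordered_and_permutation_invariant(self):
        rng = np.random.default_rng(7)
        X = np.c_[rng.normal(size=(3_000, 3))]
        y = (rng.random(3_000) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
        perm = rng.permutation(3)
        for fn in (mahalanobis_bound, bhattacharyya_bounds, knn_bounds):
            a = fn(X, y)
            b = fn(X[:, perm], y)
            for e in (a, b):
                if e.E_low is not None:
                    assert 0.0 <= e.E_low <= e.E_up
                assert 0.0 <= e.E_up <= 0.5
            assert a.E_up == pytest.approx(b.E_up, abs=1e-9)


@pytest.fixture(scope="module")
def noisy_cohort():
    cfg = GeneratorConfig(n_samples=8_000, seed=11,
                          noise_rate_comorbid=0.15,
                          noise_rate_noncomorbid=0.03)
    return pm.encode_features(pm.generate_cohort(cfg))


class TestBoundsReport:
    def test_noise_ordering_recovered_by_knn(self, noisy_cohort):
        rep = bounds_report(noisy_cohort, feature_sets=("core7",),
                            methods=("knn",), seed=0)
        ups = {e.subgroup: e.E_up for e in rep.estimates}
        assert ups["comorbid"] > ups["non_comorbid"]

    def test_full_grid_shape_and_singular_statuses(self, noisy_cohort):
        rep = bounds_report(noisy_cohort, seed=0)
        frame = rep.to_frame()
        assert len(frame) == 3 * 2 * 2   # methods x subgroups x sets
        allvar_bhat = frame[(frame.method == "bhattacharyya")
                            & (frame.variable_set == "all")]
        # full one-hot encoding makes the all-variable covariance singular
        assert (allvar_bhat.status == "singular_covariance").all()
        knn_rows = frame[frame.method == "knn"]
        assert knn_rows["E_up"].notna().all()

    def test_full_rank_reduction_enables_parametric_bounds(self, noisy_cohort):
        rep = bounds_report(noisy_cohort, feature_sets=("core7",),
                            methods=("mahalanobis", "bhattacharyya"),
                            seed=0, drop_redundant=True)
        frame = rep.to_frame()
        assert (frame.status == "ok").all()
        assert frame["E_up"].between(0, 0.5).all()

    def test_tiny_subgroup_recorded_not_raised(self):
        cfg = GeneratorConfig(n_samples=400, seed=1, comorbid_fraction=0.02)
        cohort = pm.encode_features(pm.generate_cohort(cfg))
        rep = bounds_report(cohort, feature_sets=("core7",),
                            methods=("knn",), seed=0)
        statuses = {e.subgroup: e.status for e in rep.estimates}
        assert statuses["comorbid"] == "too_few_samples"

    def test_identical_subgroups_overlap(self):
        rng = np.random.default_rng(8)
        n = 4_000
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * x))).astype(int)
        # identical distributions in both subgroups: intervals overlap
        com = rng.random(n) < 0.5
        a = knn_bounds(x[com, None], y[com], seed=0)
        b = knn_bounds(x[~com, None], y[~com], seed=0)
        assert not (a.E_low > b.E_up or b.E_low > a.E_up)
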