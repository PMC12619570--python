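import numpy as np
import pytest

from vesselvpop import (build_population, fit_mvnd, filter_negative_radii,
                        load_model, log_density, pseudoinverse,
                        resample_equal_arclength, sample_vpop, save_model)
from vesselvpop.errors import ParameterError
from vesselvpop.landmarks import LandmarkSet, PopulationMatrix


def brute_force_covariance(X: np.ndarray) -> np.ndarray:
    """Independent oracle: explicit double loop over the covariance definition."""
    n, d = X.shape
    mean = X.mean(axis=0)
    S = np.empty((d, d))
    for m in range(d):
        for q in range(d):
            acc = 0.0
            for i in range(n):
                acc += (X[i, m] - mean[m]) * (X[i, q] - mean[q])
            S[m, q] = acc / (n - 1)
    return S


def pop_from_matrix(X: np.ndarray, k: int) -> PopulationMatrix:
    return PopulationMatrix(matrix=X, k=k)


class TestFit:
    def test_identical_rows_zero_variance(self):
        row = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        model = fit_mvnd(pop_from_matrix(np.tile(row, (5, 1)), k=2))
        np.testing.assert_array_equal(model.mu, row)
        np.testing.assert_allclose(model.sigma, 0.0)
        assert model.rank == 0

    def test_two_row_hand_example(self):
        # active coords 0 and 1: covariance ((0-1)(0-1) + (2-1)(2-1)) / 1 = 2
        X = np.array([[0.0, 0, 0, 0], [2.0, 2, 0, 0]])
        model = fit_mvnd(pop_from_matrix(X, k=1))
        np.testing.assert_allclose(model.mu, [1, 1, 0, 0])
        assert model.sigma[0, 0] == pytest.approx(2.0)
        assert model.sigma[0, 1] == pytest.approx(2.0)
        assert model.sigma[2, 2] == 0.0

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(6, 12))
        model = fit_mvnd(pop_from_matrix(X, k=3))
        np.testing.assert_allclose(model.sigma, brute_force_covariance(X), atol=1e-10)

    def test_single_row_rejected(self):
        with pytest.raises(ParameterError):
            fit_mvnd(pop_from_matrix(np.zeros((1, 4)), k=1))

    def test_non_finite_rejected(self):
        X = np.zeros((3, 4))
        X[1, 2] = np.nan
        with pytest.raises(ParameterError):
            fit_mvnd(pop_from_matrix(X, k=1))


def model_with_sigma(diag: np.ndarray):
    """Model whose covariance is the given diagonal (mu = 0, exact SVD)."""
    from vesselvpop.mvnd import MVNDModel

    d = len(diag)
    order = np.argsort(diag)[::-1]
    U = np.eye(d)[:, order]
    s = np.asarray(diag, float)[order]
    tol = d * np.finfo(float).eps * (s[0] if d else 0.0)
    return MVNDModel(mu=np.zeros(d), sigma=np.diag(diag).astype(float), k=d // 4 or 1,
                     U=U, s=s, tol=tol, rank=int((s > tol).sum()), n_fit=10)


class TestPseudoinverse:
    def test_identity_covariance(self):
        model = model_with_sigma(np.ones(4))
        np.testing.assert_allclose(pseudoinverse(model), np.eye(4), atol=1e-12)

    def test_rank_deficient_diagonal(self):
        model = model_with_sigma(np.array([2.0, 0.0]))
        np.testing.assert_allclose(pseudoinverse(model), np.diag([0.5, 0.0]))

    def test_moore_penrose_identities_on_singular_fit(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5, 12))  # N < d: singular covariance
        model = fit_mvnd(pop_from_matrix(X, k=3))
        S, P = model.sigma, pseudoinverse(model)
        scale = np.abs(S).max()
        assert np.abs(S @ P @ S - S).max() <= 1e-8 * scale
        assert np.abs(P @ S @ P - P).max() <= 1e-8 * np.abs(P).max()
        assert np.abs((S @ P).T - S @ P).max() <= 1e-8
        assert np.abs((P @ S).T - P @ S).max() <= 1e-8


class TestLogDensity:
    def test_standard_normal_at_mean(self):
        d = 4
        model = model_with_sigma(np.ones(d))
        assert log_density(model, model.mu) == pytest.approx(-(d / 2) * np.log(2 * np.pi))

    def test_full_rank_matches_dense_inverse(self):
        rng = np.random.default_rng(11)
        d = 8
        X = rng.normal(size=(60, d))  # N >> d: full-rank covariance
        model = fit_mvnd(pop_from_matrix(X, k=2))
        assert model.rank == d
        p = rng.normal(size=d)
        diff = p - model.mu
        sign, logdet = np.linalg.slogdet(model.sigma)
        expected = -0.5 * (d * np.log(2 * np.pi) + logdet
                           + diff @ np.linalg.solve(model.sigma, diff))
        assert log_density(model, p) == pytest.approx(expected, abs=1e-8)

    def test_off_support_is_minus_infinity(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(3, 8))  # rank 2
        model = fit_mvnd(pop_from_matrix(X, k=2))
        off = model.U[:, -1]  # orthogonal to the support
        assert log_density(model, model.mu + off) == -np.inf

    def test_maximized_at_the_mean(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 8))
        model = fit_mvnd(pop_from_matrix(X, k=2))
        at_mu = log_density(model, model.mu)
        for _ in range(20):
            probe = model.mu + model.U[:, :model.rank] @ rng.normal(size=model.rank)
            assert log_density(model, probe) <= at_mu

    def test_length_mismatch_rejected(self):
        model = fit_mvnd(pop_from_matrix(np.random.default_rng(0).normal(size=(4, 8)), 2))
        with pytest.raises(ParameterError):
            log_density(model, np.zeros(7))


class TestSampling:
    def test_rank_zero_model_samples_equal_mu_exactly(self):
        row = np.arange(8.0)
        model = fit_mvnd(pop_from_matrix(np.tile(row, (4, 1)), k=2))
        vp = sample_vpop(model, 7, seed=0)
        assert np.array_equal(vp.pop.matrix, np.tile(row, (7, 1)))

    def test_same_seed_is_bitwise_identical(self, ica_pop_30):
        P = build_population([resample_equal_arclength(c, 10) for c in ica_pop_30])
        model = fit_mvnd(P)
        a = sample_vpop(model, 50, seed=123)
        b = sample_vpop(model, 50, seed=123)
        assert np.array_equal(a.pop.matrix, b.pop.matrix)

    def test_moment_recovery_at_n5000(self):
        rng = np.random.default_rng(21)
        A = rng.normal(size=(8, 8))
        X = rng.normal(size=(300, 8)) @ A  # known dense model, d = 8
        model = fit_mvnd(pop_from_matrix(X, k=2))
        vp = sample_vpop(model, 5000, seed=4)
        emp_mean = vp.pop.matrix.mean(axis=0)
        marginal_sd = np.sqrt(np.diag(model.sigma))
        assert np.all(np.abs(emp_mean - model.mu) <= 4 * marginal_sd / np.sqrt(5000))
        emp_cov = np.cov(vp.pop.matrix, rowvar=False, ddof=1)
        rel = np.linalg.norm(emp_cov - model.sigma) / np.linalg.norm(model.sigma)
        assert rel < 0.10

    def test_samples_lie_in_affine_support(self, ica_pop_30):
        P = build_population([resample_equal_arclength(c, 15) for c in ica_pop_30])
        model = fit_mvnd(P)
        vp = sample_vpop(model, 20, seed=2)
        U_null = model.U[:, model.rank:]
        resid = (vp.pop.matrix - model.mu) @ U_null
        assert np.abs(resid).max() < 1e-8

    def test_negative_radius_count_matches_manual_count(self, ica_pop_30):
        P = build_population([resample_equal_arclength(c, 10) for c in ica_pop_30])
        model = fit_mvnd(P)
        vp = sample_vpop(model, 200, seed=3)
        manual = int((vp.pop.matrix[:, 3 * 10:] < 0).sum())
        assert vp.negative_radius_count == manual

    def test_negative_sample_size_rejected(self, ica_pop_30):
        P = build_population([resample_equal_arclength(c, 5) for c in ica_pop_30])
        with pytest.raises(ParameterError):
            sample_vpop(fit_mvnd(P), -1, seed=0)

    def test_negative_radius_post_filters(self):
        k = 2
        rows = np.array([[0, 1, 0, 1, 0, 1, -0.5, 1.0],
                         [0, 1, 0, 1, 0, 1, 0.5, 1.0]])
        from vesselvpop.mvnd import VirtualPopulation
        vp = VirtualPopulation(pop=PopulationMatrix(matrix=rows, k=k,
                                                    ids=["a", "b"], labels=["", ""]),
                               seed=0, negative_radius_count=1)
        rejected = filter_negative_radii(vp, "reject")
        assert rejected.pop.n == 1 and rejected.pop.ids == ["b"]
        clamped = filter_negative_radii(vp, "clamp", floor=0.1)
        assert clamped.pop.matrix[0, 6] == pytest.approx(0.1)


def test_model_hdf5_round_trip(tmp_path, ica_pop_30):
    P = build_population([resample_equal_arclength(c, 8) for c in ica_pop_30])
    model = fit_mvnd(P)
    path = save_model(model, tmp_path / "model.h5")
    loaded = load_model(path)
    np.testing.assert_array_equal(loaded.mu, model.mu)
    np.testing.assert_array_equal(loaded.sigma, model.sigma)
    assert loaded.k == model.k and loaded.rank == model.rank
    assert loaded.n_fit == model.n_fit and loaded.label == model.label
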