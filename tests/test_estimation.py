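import numpy as np
import pytest

import sourcesink as ss
from sourcesink.estimation import (
    _nn_soft_threshold,
    _predict_uv,
    adaptive_weights,
    aic,
    precompute_design,
)

from oracles import brute_force_design, grid_min_1d, nnls_oracle, random_tiny_instance, rss_uv


def make_tensor(G, years=None):
    return ss.ExposureTensor(G=G, years=years or list(range(G.shape[3])))


def make_Y(y):
    I, T = y.shape
    return ss.AbundanceMatrix(y=y, n_obs=np.ones((I, T), int), years=list(range(T)))


# ---------------------------------------------------------------------------
# structural_zero_mask
# ---------------------------------------------------------------------------


class TestStructuralZeroMask:
    def test_zero_slice_masked(self):
        G = np.random.default_rng(0).uniform(0, 0.1, size=(3, 2, 4, 5))
        G[1, :, 2, :] = 0.0
        mask = ss.structural_zero_mask(make_tensor(G))
        assert mask[1, 2]
        assert mask.sum() == 1

    def test_single_positive_entry_unmasks(self):
        G = np.zeros((2, 2, 2, 2))
        G[1, 0, 1, 1] = 1e-9
        mask = ss.structural_zero_mask(make_tensor(G))
        assert not mask[1, 1]
        assert mask.sum() == 3


# ---------------------------------------------------------------------------
# precompute_design
# ---------------------------------------------------------------------------


class TestPrecomputeDesign:
    def test_constant_basis_sums_releases(self):
        rng = np.random.default_rng(1)
        G = rng.uniform(0, 0.2, size=(2, 5, 3, 4))
        Z = ss.precompute_design(make_tensor(G), ss.build_basis(5, 1))
        np.testing.assert_allclose(Z[:, 0], G.sum(axis=1), atol=1e-12)

    def test_single_entry(self):
        G = np.zeros((1, 4, 2, 3))
        G[0, 2, 1, 0] = 0.7
        basis = ss.build_basis(4, 2)
        Z = ss.precompute_design(make_tensor(G), basis)
        np.testing.assert_allclose(Z[0, :, 1, 0], basis.Phi[2] * 0.7, atol=1e-12)
        assert Z[0, :, 0, :].sum() == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        G = rng.uniform(0, 0.2, size=(2, 6, 3, 4))
        basis = ss.build_basis(6, 4)
        Z = ss.precompute_design(make_tensor(G), basis)
        np.testing.assert_allclose(Z, brute_force_design(basis.Phi, G), atol=1e-12)

    def test_dim_mismatch(self):
        G = np.zeros((1, 4, 2, 3))
        with pytest.raises(ValueError, match="release"):
            ss.precompute_design(make_tensor(G), ss.build_basis(5, 2))


# ---------------------------------------------------------------------------
# adaptive weights
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def aw_setup():
    rng = np.random.default_rng(3)
    J, I, D, K, T = 2, 3, 6, 2, 8
    G = rng.uniform(0, 0.15, size=(J, D, I, T))
    G[1, :, 0, :] = 0.0  # structural zero
    tensor = make_tensor(G)
    basis = ss.build_basis(D, K)
    Z = ss.precompute_design(tensor, basis)
    u = np.array([[1.0, 0.5, 0.0], [0.0, 2.0, 1.0]])
    v = rng.uniform(0.5, 1.5, size=(J, K))
    y = _predict_uv(u, v, Z)
    Y = make_Y(y)
    mask = ss.structural_zero_mask(tensor)
    return Y, Z, mask, tensor, basis


class TestAdaptiveWeights:

    def test_matches_pilot_formula(self, aw_setup):
        Y, Z, mask, tensor, basis = aw_setup
        opts = ss.FitOptions(seed=5)
        omega = adaptive_weights(Y, Z, mask, opts)
        pilot = ss.fit(Y, tensor, basis, lam=0.0, opts=opts)
        outer = np.abs(pilot.u[:, :, None] * pilot.v[:, None, :])
        expected = np.where(mask[:, :, None], np.inf, 1.0 / (outer + 1e-6))
        np.testing.assert_allclose(omega, expected, rtol=1e-9)

    def test_masked_get_infinite_weight(self, aw_setup):
        Y, Z, mask, *_ = aw_setup
        omega = adaptive_weights(Y, Z, mask)
        assert np.isinf(omega[mask]).all()

    def test_floor_behavior(self, aw_setup):
        # an outer-product entry of exactly 0 maps to the 1e6 ceiling
        Y, Z, mask, *_ = aw_setup
        omega = adaptive_weights(Y, Z, mask)
        finite = omega[np.isfinite(omega)]
        assert finite.max() <= 1e6 + 1e-6

    def test_monotone_in_pilot_magnitude(self, aw_setup):
        Y, Z, mask, tensor, basis = aw_setup
        opts = ss.FitOptions(seed=5)
        omega = adaptive_weights(Y, Z, mask, opts)
        pilot = ss.fit(Y, tensor, basis, lam=0.0, opts=opts)
        outer = np.abs(pilot.u[:, :, None] * pilot.v[:, None, :])
        o, w = outer[~mask[:, :, None] & np.ones_like(outer, bool)], omega[~mask[:, :, None] & np.ones_like(omega, bool)]
        order = np.argsort(o)
        assert (np.diff(w[order]) <= 1e-9).all()


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------


class TestFit:
    def test_full_shrinkage(self, noisy_fit_inputs):
        _, G, Y, basis = noisy_fit_inputs
        m = ss.fit(Y, G, basis, lam=1e12)
        assert (m.w == 0).all() and (m.u == 0).all() and (m.v == 0).all()
        assert m.rss == pytest.approx(float((Y.y[Y.observed] ** 2).sum()))

    def test_noiseless_single_source_recovery(self):
        # J=1, I=2, D=3, K=1: Y built from known (u, v); lambda=0 recovers it
        rng = np.random.default_rng(4)
        G = rng.uniform(0.05, 0.3, size=(1, 3, 2, 6))
        G /= np.maximum(G.sum(axis=2, keepdims=True), 1.0)
        tensor = make_tensor(G)
        basis = ss.build_basis(3, 1)
        Z = ss.precompute_design(tensor, basis)
        u = np.array([[1.3, 0.4]])
        v = np.array([[0.8]])
        Y = make_Y(_predict_uv(u, v, Z))
        m = ss.fit(Y, tensor, basis, lam=0.0)
        np.testing.assert_allclose(ss.predict(m, tensor), Y.y, atol=1e-6)
        # normalized truth
        w_true = u.sum() * (basis.Phi @ v[0]).sum()
        np.testing.assert_allclose(m.w, [w_true], atol=1e-6)
        np.testing.assert_allclose(m.theta[0], u[0] / u.sum(), atol=1e-6)
        np.testing.assert_allclose(m.f[0], np.full(3, 1 / 3), atol=1e-6)

    def test_grid_search_cross_check(self):
        # J=1, K=1 normalized problem has 2 free parameters (w, theta_1);
        # dense grid search over them confirms the attained minimum rss
        rng = np.random.default_rng(5)
        G = rng.uniform(0.05, 0.3, size=(1, 3, 2, 6))
        G /= np.maximum(G.sum(axis=2, keepdims=True), 1.0)
        tensor = make_tensor(G)
        basis = ss.build_basis(3, 1)
        X = G.sum(axis=1)[0] / 3.0  # f uniform over D=3
        y = 1.5 * np.array([[0.7], [0.3]]) * X + rng.normal(0, 0.01, size=X.shape)
        Y = make_Y(y)
        m = ss.fit(Y, tensor, basis, lam=0.0)
        ws = np.linspace(0.5, 3.0, 401)
        th = np.linspace(0.0, 1.0, 401)
        W, TH = np.meshgrid(ws, th, indexing="ij")
        pred = W[:, :, None, None] * np.stack([TH, 1 - TH], axis=2)[:, :, :, None] * X[None, None]
        rss_grid = ((y[None, None] - pred) ** 2).sum(axis=(2, 3))
        assert m.rss <= rss_grid.min() + 1e-6

    def test_normalization_identities(self, noisy_fit_inputs):
        _, G, Y, basis = noisy_fit_inputs
        m = ss.fit(Y, G, basis, lam=0.01)
        for j in range(len(m.w)):
            if m.w[j] > 0:
                assert m.theta[j].sum() == pytest.approx(1.0, abs=1e-8)
                assert m.f[j].sum() == pytest.approx(1.0, abs=1e-8)
        assert (m.theta >= 0).all() and (m.f >= 0).all() and (m.w >= 0).all()

    def test_fixed_zeros_respected(self):
        rng = np.random.default_rng(6)
        G = rng.uniform(0, 0.2, size=(2, 4, 3, 8))
        G[0, :, 2, :] = 0.0
        tensor = make_tensor(G)
        basis = ss.build_basis(4, 2)
        Z = ss.precompute_design(tensor, basis)
        u = np.array([[1.0, 0.8, 0.0], [0.5, 0.2, 0.9]])
        v = rng.uniform(0.5, 1.5, size=(2, 2))
        Y = make_Y(_predict_uv(u, v, Z) + rng.normal(0, 0.01, size=(3, 8)))
        m = ss.fit(Y, tensor, basis, lam=0.001)
        assert m.fixed_zero_mask[0, 2]
        assert m.theta[0, 2] == 0.0 and m.u[0, 2] == 0.0

    def test_objective_trace_monotone_without_polish(self, noisy_fit_inputs):
        _, G, Y, basis = noisy_fit_inputs
        opts = ss.FitOptions(polish=False, debug_monotone=True, n_restarts=1)
        m = ss.fit(Y, G, basis, lam=0.01, opts=opts)
        assert (np.diff(m.objective_trace) <= 1e-9).all()

    def test_rescaling_invariance_of_predictions(self, noisy_fit_inputs):
        _, G, Y, basis = noisy_fit_inputs
        m = ss.fit(Y, G, basis, lam=0.0)
        Z = ss.precompute_design(G, basis)
        c = 3.7
        np.testing.assert_allclose(
            _predict_uv(m.u * c, m.v / c, Z), _predict_uv(m.u, m.v, Z), atol=1e-9
        )

    def test_masked_cells_excluded(self):
        rng = np.random.default_rng(7)
        G = rng.uniform(0, 0.2, size=(1, 3, 2, 5))
        tensor = make_tensor(G)
        basis = ss.build_basis(3, 1)
        y = rng.uniform(0, 1, size=(2, 5))
        n_obs = np.ones((2, 5), int)
        n_obs[1, 3] = 0
        y_masked = y.copy()
        y_masked[1, 3] = 1e9  # would wreck the fit if it entered the sums
        Y = ss.AbundanceMatrix(y=np.where(n_obs > 0, y, 0), n_obs=n_obs, years=list(range(5)))
        m = ss.fit(Y, tensor, basis, lam=0.0)
        resid = (Y.y - ss.predict(m, tensor))[Y.observed]
        assert m.rss == pytest.approx(float((resid**2).sum()), rel=1e-9)
        assert m.n_obs == 9


class TestSoftThreshold:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.5, 3.0)
        b = rng.uniform(-2.0, 2.0)
        pen = rng.uniform(0.0, 2.0)
        x_hat = _nn_soft_threshold(a, b, pen)
        x_grid = grid_min_1d(a, b, pen, x_max=5.0)
        assert x_hat == pytest.approx(x_grid, abs=5e-5)

    def test_exact_zero_under_strong_penalty(self):
        assert _nn_soft_threshold(1.0, 0.3, 1.0) == 0.0


class TestLambdaZeroOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_alternating_nnls(self, seed):
        rng = np.random.default_rng(seed)
        J, I, D, K, T, G, u_true, v_true = random_tiny_instance(rng)
        tensor = make_tensor(G)
        basis = ss.build_basis(D, K)
        Z = ss.precompute_design(tensor, basis)
        y = _predict_uv(u_true, v_true, Z) + rng.normal(0, 0.05, size=(I, T))
        Y = make_Y(y)
        m = ss.fit(Y, tensor, basis, lam=0.0)
        oracle = nnls_oracle(y, Y.observed, Z, m.fixed_zero_mask, n_starts=10, seed=seed)
        assert m.objective == pytest.approx(oracle, abs=1e-6)


# ---------------------------------------------------------------------------
# aic / tune
# ---------------------------------------------------------------------------


class TestAic:
    def test_closed_form(self):
        # rss = N, df = 3 -> N*ln(1) + 6 = 6
        assert aic(rss=20.0, n_obs=20, df=3) == pytest.approx(6.0)

    def test_extra_parameter_costs_two(self):
        base = aic(rss=5.0, n_obs=20, df=3)
        assert aic(rss=5.0, n_obs=20, df=4) == pytest.approx(base + 2.0)

    def test_zero_rss_sentinel(self):
        assert aic(rss=0.0, n_obs=10, df=2) == -np.inf


class TestTune:
    def test_grid_of_zero_matches_fit(self, noisy_fit_inputs):
        _, G, Y, basis = noisy_fit_inputs
        mt = ss.tune(Y, G, basis, np.array([0.0]))
        m0 = ss.fit(Y, G, basis, lam=0.0)
        np.testing.assert_allclose(mt.w, m0.w, atol=1e-10)
        np.testing.assert_allclose(mt.theta, m0.theta, atol=1e-10)
        assert mt.aic == pytest.approx(m0.aic)

    def test_deterministic(self, noisy_fit_inputs):
        _, G, Y, basis = noisy_fit_inputs
        grid = np.array([0.0, 0.01, 0.1])
        a = ss.tune(Y, G, basis, grid, opts=ss.FitOptions(seed=11))
        b = ss.tune(Y, G, basis, grid, opts=ss.FitOptions(seed=11))
        assert a.tuning_path == b.tuning_path
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_never_all_zero_when_signal_exists(self, noisy_fit_inputs):
        _, G, Y, basis = noisy_fit_inputs
        m = ss.tune(Y, G, basis, np.array([0.0, 1e12]))
        assert m.w.sum() > 0  # the null fit loses on AIC

    def test_aic_tuning_recovers_zeros_better_than_unpenalized(self, noisy_fit_inputs):
        cfg, G, Y, basis = noisy_fit_inputs
        true_zero = cfg.true_theta == 0
        mask = ss.structural_zero_mask(G)
        comparable = true_zero & ~mask
        m0 = ss.fit(Y, G, basis, lam=0.0)
        mt = ss.tune(Y, G, basis, np.array([0.0, 1e-3, 1e-2, 1e-1, 1.0]))
        fp0 = int((m0.theta[comparable] > 0).sum())
        fpt = int((mt.theta[comparable] > 0).sum())
        assert fpt <= fp0

    def test_empty_grid_rejected(self, noisy_fit_inputs):
        _, G, Y, basis = noisy_fit_inputs
        with pytest.raises(ValueError):
            ss.tune(Y, G, basis, np.array([]))


# ---------------------------------------------------------------------------
# predict / productivity
# ---------------------------------------------------------------------------


def manual_fit(w, theta, f, mask=None):
    w = np.asarray(w, float)
    theta = np.asarray(theta, float)
    f = np.asarray(f, float)
    J, I = theta.shape
    K = 1
    return ss.ModelFit(
        w=w, theta=theta, f=f, b=np.zeros((J, K)), u=theta * w[:, None], v=np.ones((J, K)),
        lam=np.zeros(J), omega=np.ones((J, I, K)),
        fixed_zero_mask=np.zeros((J, I), bool) if mask is None else mask,
        rss=0.0, df=0, aic=0.0, objective=0.0,
        objective_trace=np.zeros(1), converged=True, n_obs=I,
    )


class TestPredict:
    def test_zero_G_gives_zero(self):
        m = manual_fit([2.0], [[1.0, 0.0]], [[0.5, 0.5]])
        G = make_tensor(np.zeros((1, 2, 2, 3)))
        np.testing.assert_array_equal(ss.predict(m, G), np.zeros((2, 3)))

    def test_hand_arithmetic(self):
        # w=2, theta=(1,0), f point mass at d=2, G[1,2,1,t]=0.5 -> 1.0
        m = manual_fit([2.0], [[1.0, 0.0]], [[0.0, 1.0, 0.0]])
        G = np.zeros((1, 3, 2, 4))
        G[0, 1, 0, :] = 0.5
        np.testing.assert_allclose(ss.predict(m, make_tensor(G))[0], 1.0)
        np.testing.assert_allclose(ss.predict(m, make_tensor(G))[1], 0.0)

    def test_reproduces_training_rss(self, noisy_fit_inputs):
        _, G, Y, basis = noisy_fit_inputs
        m = ss.fit(Y, G, basis, lam=0.0)
        resid = (Y.y - ss.predict(m, G))[Y.observed]
        assert float((resid**2).sum()) == pytest.approx(m.rss, rel=1e-6)

    def test_dim_mismatch(self):
        m = manual_fit([1.0], [[0.5, 0.5]], [[1.0]])
        with pytest.raises(ValueError):
            ss.predict(m, make_tensor(np.zeros((2, 1, 2, 1))))


class TestSourceProductivity:
    def test_inactive_source_zero(self):
        m = manual_fit([0.0, 1.0], [[0, 0], [1, 0]], [[1.0], [1.0]])
        assert ss.source_productivity(m)[0] == 0.0

    def test_scale_equivariance(self, noiseless_fit_inputs):
        _, G, Y, basis = noiseless_fit_inputs
        m1 = ss.fit(Y, G, basis, lam=0.0)
        Y2 = ss.AbundanceMatrix(y=2 * Y.y, n_obs=Y.n_obs, years=list(Y.years), mask=Y.mask)
        m2 = ss.fit(Y2, G, basis, lam=0.0)
        np.testing.assert_allclose(m2.w, 2 * m1.w, rtol=1e-4)

    def test_ordering_matches_truth(self, noiseless_fit_inputs):
        cfg, G, Y, basis = noiseless_fit_inputs
        m = ss.fit(Y, G, basis, lam=0.0)
        assert np.argsort(m.w).tolist() == np.argsort(cfg.true_w).tolist()
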