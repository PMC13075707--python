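"""The sparse-CCA network: losses, adaptive weights, training contracts."""

import numpy as np
import pytest

from adscca.dscca import (DsccaParams, TrainConfig, canonical_variate,
                          compute_loss_components, encode, encode_y,
                          extract_support, task_weights, train_dscca)
from adscca.errors import BatchTooSmallError, ShapeError
from adscca.nn import Tensor, gradcheck

rng = np.random.default_rng(0)


class TestTaskWeights:
    def test_sigma_sqrt_half_gives_unit_weight(self):
        # σ = √0.5 → λ = 1/(2·0.5) = 1; invert softplus to get raw
        target = np.sqrt(0.5) - 1e-3
        raw = np.log(np.expm1(target))
        lam, sig = task_weights(np.full(4, raw))
        assert np.allclose(lam, 1.0, atol=1e-10)

    def test_doubling_sigma_quarters_lambda(self):
        lam1, sig1 = task_weights(np.zeros(4))
        raw2 = np.log(np.expm1(2 * sig1 - 1e-3))
        lam2, _ = task_weights(raw2)
        assert np.allclose(lam2, lam1 / 4, rtol=1e-9)

    def test_raw_zero_closed_form(self):
        lam, sig = task_weights(np.zeros(4))
        expected_sigma = np.log(2) + 1e-3
        assert np.allclose(sig, expected_sigma)
        assert np.allclose(lam, 1 / (2 * expected_sigma ** 2))

    def test_always_positive(self):
        lam, _ = task_weights(np.array([-30.0, -5.0, 0.0, 30.0]))
        assert (lam > 0).all()


class TestEncode:
    def test_identity_linear_encoder_reproduces_input(self):
        cfg = TrainConfig(linear_limit=True, seed=0)
        params = DsccaParams(6, 6, cfg)
        params.encoder_x.lin0.W.data = np.eye(6)  # exact identity
        x = rng.normal(size=(5, 6))
        assert np.allclose(encode(params, x), x)

    def test_gene_local_encoder_starts_at_identity(self):
        params = DsccaParams(8, 8, TrainConfig(seed=1))
        x = rng.normal(size=(4, 8))
        assert np.allclose(encode(params, x), x)  # zero-init branch

    def test_inference_deterministic_and_batch1(self):
        params = DsccaParams(5, 5, TrainConfig(seed=2, encoder="dense"))
        x = rng.normal(size=(1, 5))
        h1, h2 = encode(params, x), encode(params, x)
        assert np.array_equal(h1, h2) and np.isfinite(h1).all()

    def test_shape_errors(self):
        params = DsccaParams(5, 4, TrainConfig(seed=3))
        with pytest.raises(ShapeError):
            encode(params, rng.normal(size=(3, 7)))
        with pytest.raises(ShapeError):
            encode_y(params, rng.normal(size=(3, 7)))


class TestCanonicalVariate:
    def test_reduces_to_linear_projection(self):
        X = rng.normal(size=(7, 4))
        u = rng.normal(size=4)
        assert np.allclose(canonical_variate(X, u), X @ u)

    def test_zero_and_onehot_weights(self):
        H = rng.normal(size=(6, 3))
        assert np.allclose(canonical_variate(H, np.zeros(3)), 0)
        w = np.array([0.0, 1.0, 0.0])
        assert np.allclose(canonical_variate(H, w), H[:, 1])

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            canonical_variate(rng.normal(size=(5, 3)), np.ones(4))


class TestLossComponents:
    def _params(self, p=6, q=6, **kw):
        return DsccaParams(p, q, TrainConfig(seed=4, **kw))

    def test_perfect_correlation_bound(self):
        params = self._params()
        params.u.data = np.ones(6)
        params.v.data = np.ones(6)
        x = rng.normal(size=(10, 6))
        bd = compute_loss_components(params, x, x)  # identical views
        assert bd.l_corr == pytest.approx(-1.0, abs=1e-6)

    def test_zero_weights_zero_sparsity(self):
        params = self._params()
        params.u.data[:] = 0.0
        params.v.data[:] = 0.0
        bd = compute_loss_components(params, rng.normal(size=(8, 6)),
                                     rng.normal(size=(8, 6)))
        assert bd.l_sparse == 0.0

    def test_corr_matches_direct_pearson(self):
        params = self._params(p=3, q=3)
        x = rng.normal(size=(5, 3))
        y = rng.normal(size=(5, 3))
        bd = compute_loss_components(params, x, y)
        tx, ty = x @ params.u.data, y @ params.v.data  # identity encoders
        r = np.corrcoef(tx, ty)[0, 1]
        assert bd.l_corr == pytest.approx(-r, abs=1e-6)

    def test_loss_ranges(self):
        params = self._params()
        bd = compute_loss_components(params, rng.normal(size=(12, 6)),
                                     rng.normal(size=(12, 6)))
        assert -1.0 <= bd.l_corr <= 1.0
        assert bd.l_sparse >= 0 and bd.l_recon >= 0 and bd.l_norm >= 0
        assert bd.total == pytest.approx(
            sum(l * c for l, c in zip(bd.lambdas,
                                      (bd.l_corr, bd.l_sparse,
                                       bd.l_recon, bd.l_norm))), rel=1e-10)

    def test_batch_too_small(self):
        params = self._params()
        with pytest.raises(BatchTooSmallError):
            compute_loss_components(params, rng.normal(size=(2, 6)),
                                    rng.normal(size=(2, 6)))

    def test_zero_variance_variate_guarded(self):
        params = self._params()
        params.u.data[:] = 0.0
        x = rng.normal(size=(8, 6))
        bd = compute_loss_components(params, x, x)
        assert np.isfinite(bd.l_corr)

    def test_gradient_wrt_u_matches_finite_differences(self):
        from adscca.dscca import _loss_graph
        params = DsccaParams(5, 5, TrainConfig(seed=5))
        x = Tensor(rng.normal(size=(6, 5)))
        y = Tensor(rng.normal(size=(6, 5)))
        params.eval()
        u0 = params.u.data.copy()
        params.zero_grad()
        obj, _ = _loss_graph(params, x, y)
        obj.backward()
        analytic = params.u.grad.copy()
        eps = 1e-6
        for j in range(5):
            params.u.data = u0.copy()
            params.u.data[j] += eps
            hi, _ = _loss_graph(params, x, y)
            params.u.data = u0.copy()
            params.u.data[j] -= eps
            lo, _ = _loss_graph(params, x, y)
            num = (hi.item() - lo.item()) / (2 * eps)
            assert num == pytest.approx(analytic[j], rel=1e-4, abs=1e-8)
        params.u.data = u0


class TestTraining:
    def _data(self, n=60, p=10, seed=6):
        r = np.random.default_rng(seed)
        z = r.normal(size=n)
        X = np.outer(z, r.normal(size=p)) + r.normal(size=(n, p))
        Y = np.outer(z, r.normal(size=p)) + r.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)
        Y = (Y - Y.mean(0)) / Y.std(0)
        return X, Y

    def test_zero_epochs_returns_initialization(self):
        X, Y = self._data()
        cfg = TrainConfig(epochs=0, seed=7)
        params, trace = train_dscca(X, Y, cfg=cfg)
        init = DsccaParams(10, 10, cfg)
        assert np.allclose(params.u.data, init.u.data)
        assert len(trace) == 0

    def test_same_seed_reproducible(self):
        X, Y = self._data()
        cfg = TrainConfig(epochs=15, batch_size=16, seed=8)
        p1, _ = train_dscca(X, Y, cfg=cfg)
        p2, _ = train_dscca(X, Y, cfg=cfg)
        assert np.allclose(p1.u.data, p2.u.data, atol=1e-6)

    def test_lambdas_positive_and_bounded_throughout(self):
        X, Y = self._data()
        _, trace = train_dscca(X, Y, cfg=TrainConfig(epochs=25, seed=9))
        lam = np.asarray(trace.lambdas)
        assert (lam > 0).all()
        assert (lam < 1 / (2 * 1e-3 ** 2)).all()

    def test_correlation_increases_on_shared_factor(self):
        X, Y = self._data()
        _, trace = train_dscca(X, Y, cfg=TrainConfig(epochs=150, seed=10,
                                                     lr=3e-3,
                                                     batch_size=None))
        assert abs(trace.train_corr[-1]) > abs(trace.train_corr[0])
        assert abs(trace.train_corr[-1]) > 0.5

    def test_validation_corr_tracked(self):
        X, Y = self._data(n=80)
        cfg = TrainConfig(epochs=5, seed=11)
        _, trace = train_dscca(X[:60], Y[:60], X[60:], Y[60:], cfg)
        assert len(trace.val_corr) == 5

    def test_linear_limit_matches_closed_form_cca_small(self):
        """Desk-scale version of the linear-limit equivalence: trained
        correlation within 0.05 of the generalized-eigenproblem value."""
        import scipy.linalg as sla
        X, Y = self._data(n=200, p=8, seed=12)
        cfg = TrainConfig(epochs=300, batch_size=None, linear_limit=True,
                          lr=5e-3, fixed_lambdas=(1.0, 0.0, 1e-3, 1e-3),
                          weight_decay=0.0, seed=13)
        _, trace = train_dscca(X, Y, cfg=cfg)
        n = X.shape[0]
        Sxx = X.T @ X / n + 1e-8 * np.eye(8)
        Syy = Y.T @ Y / n + 1e-8 * np.eye(8)
        Sxy = X.T @ Y / n
        M = sla.solve(Sxx, Sxy) @ sla.solve(Syy, Sxy.T)
        rho = np.sqrt(np.max(sla.eigvals(M).real))
        assert abs(trace.train_corr[-1]) == pytest.approx(rho, abs=0.05)

    def test_sparsity_pressure_shrinks_support(self):
        """Raising the sparsity weight (fixed-λ mode) never enlarges the
        selected support on the same data."""
        X, Y = self._data(n=80, p=12, seed=14)
        sizes = []
        for lam2 in (0.05, 0.5, 2.0):
            cfg = TrainConfig(epochs=60, batch_size=None, seed=15,
                              fixed_lambdas=(1.0, lam2, 0.1, 0.1),
                              epsilon_select=0.05)
            params, _ = train_dscca(X, Y, cfg=cfg)
            sx, _ = extract_support(params)
            sizes.append(len(sx))
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestExtractSupport:
    def _with_u(self, u):
        params = DsccaParams(len(u), len(u), TrainConfig(seed=16))
        params.u.data = np.asarray(u, float)
        return params

    def test_single_nonzero(self):
        sx, _ = extract_support(self._with_u([1.0, 0.0, 0.0]), 0.001)
        assert sx.tolist() == [0]

    def test_zero_threshold_dense(self):
        sx, _ = extract_support(self._with_u([0.5, -0.2, 0.1]), 0.0)
        assert sx.tolist() == [0, 1, 2]

    def test_threshold_arithmetic(self):
        sx, _ = extract_support(self._with_u([1.0, 0.5, 1e-6]), 1e-3)
        assert sx.tolist() == [0, 1]

    def test_all_zero_warns_empty(self):
        params = self._with_u([0.0, 0.0])
        params.v.data[:] = 0.0
        with pytest.warns(UserWarning):
            sx, sy = extract_support(params, 0.01)
        assert sx.size == 0 and sy.size == 0
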