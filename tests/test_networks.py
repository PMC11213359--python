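"""Flow bijectivity, Jacobians, summary network, checkpoint round trip."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flowmiss as fm
from flowmiss.autodiff import Tensor, check_gradients
from flowmiss.networks import ArchConfig, CouplingLayer, LSTMSummary


def _randomize(flow, rng, scale=0.3):
    """Give the zero-initialized final layers nonzero weights."""
    for name, p in flow.params().items():
        if p.v.ndim == 2 and not p.v.any():
            p.v = rng.normal(0, scale / np.sqrt(p.v.shape[0]), size=p.v.shape)
    return flow


def _fd_logdet(fn, theta, eps=1e-6):
    """log|det| of the Jacobian of theta -> fn(theta) by central differences."""
    n = theta.size
    jac = np.empty((n, n))
    for j in range(n):
        up, dn = theta.copy(), theta.copy()
        up[j] += eps
        dn[j] -= eps
        jac[:, j] = (fn(up) - fn(dn)) / (2 * eps)
    return np.linalg.slogdet(jac)[1]


class TestCouplingLayer:
    def test_zero_init_is_identity(self, rng):
        layer = CouplingLayer(4, 3, rng)
        u, h = rng.standard_normal((6, 4)), rng.standard_normal((6, 3))
        v, logdet = layer.forward_np(u, h)
        np.testing.assert_allclose(v, u)
        np.testing.assert_allclose(logdet, 0.0)

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=25, deadline=None)
    def test_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        layer = CouplingLayer(3, 2, rng, hidden=(16,))
        for net in (layer.s1, layer.t1, layer.s2, layer.t2):
            net.weights[-1].v = rng.normal(0, 0.3, size=net.weights[-1].v.shape)
        u, h = rng.standard_normal((5, 3)), rng.standard_normal((5, 2))
        v, _ = layer.forward_np(u, h)
        np.testing.assert_allclose(layer.inverse_np(v, h), u, atol=1e-10)
        np.testing.assert_allclose(layer.forward_np(layer.inverse_np(v, h), h)[0], v, atol=1e-10)

    def test_inverse_with_wrong_condition_fails(self, rng):
        layer = CouplingLayer(2, 2, rng)
        for net in (layer.s1, layer.t1, layer.s2, layer.t2):
            net.weights[-1].v = rng.normal(0, 0.5, size=net.weights[-1].v.shape)
        u = rng.standard_normal((1, 2))
        h, h_other = rng.standard_normal((1, 2)), rng.standard_normal((1, 2))
        v, _ = layer.forward_np(u, h)
        assert not np.allclose(layer.inverse_np(v, h_other), u, atol=1e-6)

    @pytest.mark.parametrize("n_theta", [2, 3])
    def test_logdet_matches_finite_difference_jacobian(self, rng, n_theta):
        layer = CouplingLayer(n_theta, 2, rng, hidden=(8,))
        for net in (layer.s1, layer.t1, layer.s2, layer.t2):
            net.weights[-1].v = rng.normal(0, 0.4, size=net.weights[-1].v.shape)
        theta = rng.standard_normal(n_theta)
        h = rng.standard_normal((1, 2))
        _, logdet = layer.forward_np(theta[None, :], h)
        fd = _fd_logdet(lambda t: layer.forward_np(t[None, :], h)[0][0], theta)
        assert abs(logdet[0] - fd) < 1e-5


class TestConditionalFlow:
    def _flow(self, rng, n_theta=2, randomize=True, K=5):
        arch = ArchConfig(n_coupling_layers=K, st_hidden=(16,), lstm_hidden=3)
        flow, _ = fm.init_networks(n_theta, 4, arch, rng)
        if randomize:
            _randomize(flow, rng)
        return flow

    def test_zero_init_flow_is_permutation_with_zero_logdet(self, rng):
        flow = self._flow(rng, randomize=False)
        theta = rng.standard_normal((7, 2))
        h = rng.standard_normal((7, 3))
        z, logdet = flow.forward_np(theta, h)
        # z must be theta with the fixed permutations composed in order
        expected = theta
        for p in flow.perms:
            expected = expected[:, p]
        np.testing.assert_allclose(z, expected)
        np.testing.assert_allclose(logdet, 0.0)
        np.testing.assert_allclose(flow.inverse_np(z, h), theta, atol=1e-12)

    @pytest.mark.parametrize("n_theta", [2, 3])
    def test_round_trip(self, rng, n_theta):
        flow = self._flow(rng, n_theta=n_theta)
        theta = rng.standard_normal((10, n_theta))
        h = rng.standard_normal((10, 3))
        z, _ = flow.forward_np(theta, h)
        np.testing.assert_allclose(flow.inverse_np(z, h), theta, atol=1e-8)

    @pytest.mark.parametrize("n_theta", [2, 3])
    def test_total_logdet_matches_finite_differences(self, rng, n_theta):
        flow = self._flow(rng, n_theta=n_theta, K=3)
        theta = rng.standard_normal(n_theta)
        h = rng.standard_normal((1, 3))
        _, logdet = flow.forward_np(theta[None, :], h)
        fd = _fd_logdet(lambda t: flow.forward_np(t[None, :], h)[0][0], theta)
        assert abs(logdet[0] - fd) < 1e-5

    def test_logdet_additivity(self, rng):
        flow = self._flow(rng, K=4)
        theta = rng.standard_normal((6, 2))
        h = rng.standard_normal((6, 3))
        _, total = flow.forward_np(theta, h)
        u, acc = theta, 0.0
        for k, layer in enumerate(flow.layers):
            u, ld = layer.forward_np(u, h)
            acc = acc + ld
            if k < len(flow.perms):
                u = u[:, flow.perms[k]]
        np.testing.assert_allclose(total, acc)

    def test_conditional_density_integrates_to_one(self, rng):
        """Change-of-variables density on a fine 2-D grid sums to 1."""
        flow = self._flow(rng)
        h = rng.standard_normal((1, 3))
        axis = np.linspace(-8, 8, 321)
        gx, gy = np.meshgrid(axis, axis, indexing="ij")
        nodes = np.column_stack([gx.ravel(), gy.ravel()])
        logp = flow.log_density_np(nodes, np.repeat(h, nodes.shape[0], axis=0))
        integral = np.exp(logp).sum() * (axis[1] - axis[0]) ** 2
        assert abs(integral - 1.0) < 0.01

    def test_untrained_flow_maps_normal_to_normal(self, rng):
        flow = self._flow(rng, randomize=False)
        z = rng.standard_normal((10**5, 2))
        h = np.zeros((10**5, 3))
        theta = flow.inverse_np(z, h)
        assert np.all(np.abs(theta.mean(axis=0)) < 4 / np.sqrt(10**5))
        np.testing.assert_allclose(np.cov(theta.T), np.eye(2), atol=0.02)

    def test_tape_and_numpy_paths_agree(self, rng):
        flow = self._flow(rng)
        theta = rng.standard_normal((5, 2))
        h = rng.standard_normal((5, 3))
        z_t, ld_t = flow.forward(Tensor(theta), Tensor(h))
        z_np, ld_np = flow.forward_np(theta, h)
        np.testing.assert_allclose(z_t.v, z_np)
        np.testing.assert_allclose(ld_t.v, ld_np)


class TestSummaryNetwork:
    def test_deterministic_and_fixed_size(self, rng):
        net = LSTMSummary(2, 8, rng)
        x_short = rng.standard_normal((1, 2, 2))
        x_long = rng.standard_normal((1, 41, 2))
        assert net.forward_np(x_short).shape == (1, 8)
        assert net.forward_np(x_long).shape == (1, 8)
        np.testing.assert_array_equal(net.forward_np(x_long), net.forward_np(x_long))

    def test_order_sensitivity(self, rng):
        net = LSTMSummary(1, 8, rng)
        x = rng.standard_normal((1, 10, 1))
        assert not np.allclose(net.forward_np(x), net.forward_np(x[:, ::-1, :]))

    def test_tape_and_numpy_paths_agree(self, rng):
        net = LSTMSummary(3, 4, rng)
        x = rng.standard_normal((6, 5, 3))
        np.testing.assert_allclose(net.forward(x).v, net.forward_np(x))

    def test_empty_sequence_summarizes_to_zero(self, rng):
        net = LSTMSummary(2, 4, rng)
        assert np.all(net.forward_np(np.empty((1, 0, 2))) == 0.0)


class TestInitAndCheckpoint:
    def test_default_architecture(self, rng):
        flow, summary = fm.init_networks(2, 2, rng=rng)
        assert len(flow.layers) == 5
        assert (flow.layers[0].d1, flow.layers[0].d2) == (1, 1)

    def test_odd_dimension_split(self, rng):
        flow, _ = fm.init_networks(3, 2, rng=rng)
        assert (flow.layers[0].d1, flow.layers[0].d2) == (2, 1)

    def test_seeded_init_identical(self):
        f1, s1 = fm.init_networks(2, 2, rng=np.random.default_rng(9))
        f2, s2 = fm.init_networks(2, 2, rng=np.random.default_rng(9))
        for (n1, p1), (n2, p2) in zip(
            sorted({**f1.params(), **s1.params()}.items()),
            sorted({**f2.params(), **s2.params()}.items()),
        ):
            assert n1 == n2
            np.testing.assert_array_equal(p1.v, p2.v)

    def test_checkpoint_round_trip_bit_exact(self, rng, tmp_path):
        flow, summary = fm.init_networks(2, 2, ArchConfig(st_hidden=(8,), lstm_hidden=4), rng)
        _randomize(flow, rng)
        amor = fm.Amortizer(
            flow=flow,
            summary=summary,
            encoding="E2",
            c=-1.0,
            time_grid=np.array([0.0, 5.0, 10.0]),
            theta_mean=np.array([-0.75, -0.75]),
            theta_std=np.array([0.25, 0.25]),
            meta={"model": "conversion_reaction"},
        )
        path = tmp_path / "ckpt.h5"
        fm.save_checkpoint(path, amor)
        back = fm.load_checkpoint(path)
        assert back.encoding == "E2" and back.c == -1.0
        for name, p in amor.params().items():
            np.testing.assert_array_equal(back.params()[name].v, p.v)
        x = rng.standard_normal((4, 3, 2))
        h = back.summary.forward_np(x)
        np.testing.assert_array_equal(h, amor.summary.forward_np(x))
        z = rng.standard_normal((4, 2))
        np.testing.assert_array_equal(back.flow.inverse_np(z, h), amor.flow.inverse_np(z, h))


class TestAutodiff:
    def test_gradients_match_finite_differences(self, rng):
        """End-to-end gradient check through LSTM + coupling flow + loss."""
        arch = ArchConfig(n_coupling_layers=2, st_hidden=(4,), lstm_hidden=3)
        flow, summary = fm.init_networks(2, 2, arch, rng)
        _randomize(flow, rng, scale=0.5)
        theta = rng.standard_normal((3, 2))
        x = rng.standard_normal((3, 4, 2))

        def fn():
            return fm.loss_batch(theta, x, flow, summary)

        params = list({**flow.params(), **summary.params()}.values())
        # eps balances truncation against float64 roundoff in the loss
        assert check_gradients(fn, params, eps=1e-5) < 1e-4
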