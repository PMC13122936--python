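"""Network forward passes, loss components, and gradient integrity."""

import numpy as np
import pytest
from autograd import grad
from autograd.misc import flatten

from scziva import (
    Architecture,
    ConvSpec,
    LossBreakdown,
    conv1d_forward,
    decode,
    encode,
    kl_divergence,
    masked_mse,
    reparameterize,
    total_loss,
)
from scziva.model import LatentPosterior, init_params, loss_components


@pytest.fixture
def tiny_arch():
    return Architecture(n_genes=20, kernel_size=5, stride=1, out_channels=1,
                        hidden_dim=8, latent_dim=4)


@pytest.fixture
def tiny_setup(tiny_arch):
    rng = np.random.default_rng(3)
    params = init_params(tiny_arch, rng)
    X = rng.poisson(2.0, size=(4, 20)).astype(float)
    eps = rng.standard_normal((4, 4))
    return params, X, eps, tiny_arch


class TestConv1d:
    def test_hand_arithmetic(self):
        spec = ConvSpec(2, 1, 1, weights=np.array([[1.0, 1.0]]), bias=np.array([0.0]))
        out = conv1d_forward(np.array([1.0, 2.0, 3.0]), spec)
        np.testing.assert_allclose(out, [[3.0, 5.0]])

    def test_one_hot_filter_is_a_shift(self):
        w = np.zeros((1, 3))
        w[0, 0] = 1.0
        spec = ConvSpec(3, 1, 1, weights=w, bias=np.array([0.0]))
        x = np.arange(10.0)
        out = conv1d_forward(x, spec)
        np.testing.assert_allclose(out[0], x[:8])

    def test_output_length_formula(self):
        spec = ConvSpec(64, 1, 1, weights=np.zeros((1, 64)), bias=np.zeros(1))
        out = conv1d_forward(np.zeros(100), spec)
        assert out.shape == (1, 37)
        assert spec.out_length(100) == 37

    def test_kernel_longer_than_input_errors(self):
        spec = ConvSpec(5, 1, 1, weights=np.zeros((1, 5)), bias=np.zeros(1))
        with pytest.raises(ValueError):
            conv1d_forward(np.zeros(3), spec)


class TestEncodeDecode:
    def test_shapes_and_determinism(self, tiny_setup):
        params, X, _, arch = tiny_setup
        post = encode(params, X, arch)
        assert post.mu.shape == (4, 4) and post.log_var.shape == (4, 4)
        # identical rows give identical posteriors
        X2 = np.vstack([X[0], X[0]])
        p2 = encode(params, X2, arch)
        np.testing.assert_array_equal(p2.mu[0], p2.mu[1])

    def test_all_zero_row_is_finite(self, tiny_setup):
        params, _, _, arch = tiny_setup
        post = encode(params, np.zeros((1, 20)), arch)
        assert np.isfinite(post.mu).all() and np.isfinite(post.log_var).all()

    def test_decode_codomain(self, tiny_setup):
        params, _, _, arch = tiny_setup
        rng = np.random.default_rng(0)
        for scale in (1.0, 1e3):
            z = rng.standard_normal((3, 4)) * scale
            p = decode(params, z, arch)
            assert np.all((p.pi > 0) & (p.pi < 1))
            assert np.all(p.mu > 0) and np.all(p.theta > 0)
            assert np.isfinite(p.mu).all() and np.isfinite(p.theta).all()

    def test_activation_fixed_points(self):
        # sigmoid(0) = 1/2, softplus(0) = log 2
        from scziva.model import _sigmoid, _softplus

        assert _sigmoid(np.array(0.0)) == pytest.approx(0.5)
        assert _softplus(np.array(0.0)) == pytest.approx(np.log(2.0))


class TestReparameterize:
    def test_eps_zero_returns_mean(self):
        post = LatentPosterior(np.ones((2, 3)), np.zeros((2, 3)))
        np.testing.assert_array_equal(reparameterize(post, np.zeros((2, 3))), post.mu)

    def test_unit_logvar_shift(self):
        post = LatentPosterior(np.ones((1, 2)), np.zeros((1, 2)))
        np.testing.assert_allclose(reparameterize(post, np.ones((1, 2))), 2.0 * np.ones((1, 2)))

    def test_shape_mismatch(self):
        post = LatentPosterior(np.ones((2, 3)), np.zeros((2, 3)))
        with pytest.raises(ValueError):
            reparameterize(post, np.zeros((3, 2)))


class TestKL:
    def test_prior_with_itself_is_zero(self):
        post = LatentPosterior(np.zeros((5, 3)), np.zeros((5, 3)))
        assert kl_divergence(post) == pytest.approx(0.0)

    def test_hand_value(self):
        post = LatentPosterior(np.array([[1.0]]), np.array([[0.0]]))
        assert kl_divergence(post) == pytest.approx(0.5)

    def test_monte_carlo_oracle(self):
        rng = np.random.default_rng(5)
        mu = rng.normal(0, 1, size=(1, 3))
        log_var = rng.normal(0, 0.5, size=(1, 3))
        post = LatentPosterior(mu, log_var)
        sigma = np.exp(0.5 * log_var)
        z = mu + sigma * rng.standard_normal((1_000_000, 3))
        log_q = (-0.5 * ((z - mu) / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)).sum(1)
        log_p = (-0.5 * z**2 - 0.5 * np.log(2 * np.pi)).sum(1)
        draws = log_q - log_p
        mc, se = draws.mean(), draws.std() / np.sqrt(draws.size)
        assert abs(kl_divergence(post) - mc) < 3 * se + 1e-12


class TestMaskedMSE:
    def test_perfect_reconstruction_is_zero(self):
        x = np.array([[2.0, 0.0], [3.0, 1.0]])
        pi = np.full_like(x, 0.5)
        mu = 2.0 * x  # (1-pi)*mu == x on the nonzero support
        assert masked_mse(x, pi, mu) == pytest.approx(0.0)

    def test_single_entry_arithmetic(self):
        x = np.array([[2.0]])
        assert masked_mse(x, np.array([[0.5]]), np.array([[2.0]])) == pytest.approx(1.0)

    def test_all_zero_matrix_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert masked_mse(np.zeros((2, 2)), np.full((2, 2), 0.5), np.ones((2, 2))) == 0.0


class TestTotalLoss:
    def test_unit_lambda_kills_penalty(self, tiny_setup):
        params, X, eps, arch = tiny_setup
        post = encode(params, X, arch)
        p = decode(params, reparameterize(post, eps), arch)
        bd = total_loss(X, p, post, lambda_weight=1.0, lambda_reg=1e-3)
        assert bd.penalty == 0.0

    def test_lambda_linearity(self, tiny_setup):
        params, X, eps, arch = tiny_setup
        post = encode(params, X, arch)
        p = decode(params, reparameterize(post, eps), arch)
        lo = total_loss(X, p, post, 0.5, 0.0)
        hi = total_loss(X, p, post, 1.5, 0.0)
        assert hi.total - lo.total == pytest.approx(1.0 * lo.mse, rel=1e-12)

    def test_components_reassemble(self, tiny_setup):
        params, X, eps, arch = tiny_setup
        total, zinb, kl, mse, pen = loss_components(params, X, eps, arch, 1e-3)
        bd = LossBreakdown(zinb=float(zinb), kl=float(kl), mse=float(mse),
                           lambda_weight=float(params["lam"]), penalty=float(pen))
        assert bd.total == pytest.approx(float(total), rel=1e-12)

    def test_inconsistent_breakdown_rejected(self):
        with pytest.raises(ValueError):
            LossBreakdown(zinb=1.0, kl=1.0, mse=1.0, lambda_weight=1.0,
                          penalty=0.0, total=100.0)

    def test_forward_determinism(self, tiny_setup):
        params, X, eps, arch = tiny_setup
        a = loss_components(params, X, eps, arch, 1e-3)[0]
        b = loss_components(params, X, eps, arch, 1e-3)[0]
        assert float(a) == float(b)


@pytest.mark.parametrize("variant", ["full", "no_cnn"])
def test_gradient_matches_central_differences(variant):
    """Reverse-mode gradients vs finite differences, per parameter block."""
    arch = Architecture(n_genes=20, kernel_size=5, stride=1, out_channels=1,
                        hidden_dim=8, latent_dim=4, variant=variant)
    rng = np.random.default_rng(11)
    params = init_params(arch, rng)
    X = rng.poisson(2.0, size=(4, 20)).astype(float)
    eps = rng.standard_normal((4, 4))

    def objective(p):
        return loss_components(p, X, eps, arch, 1e-3)[0]

    analytic = grad(objective)(params)
    flat, unflatten = flatten(params)
    h = 1e-5

    def obj_flat(v):
        return float(objective(unflatten(v)))

    fd_flat = np.zeros_like(flat)
    for i in range(flat.size):
        up, dn = flat.copy(), flat.copy()
        up[i] += h
        dn[i] -= h
        fd_flat[i] = (obj_flat(up) - obj_flat(dn)) / (2 * h)
    fd = unflatten(fd_flat)
    for key in params:
        ga = np.atleast_1d(np.asarray(analytic[key], dtype=float))
        gf = np.atleast_1d(np.asarray(fd[key], dtype=float))
        rel = np.linalg.norm(ga - gf) / (np.linalg.norm(gf) + 1e-12)
        assert rel < 1e-4, f"block {key}: rel err {rel:.2e}"
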