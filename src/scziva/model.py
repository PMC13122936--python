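"""Convolution-enhanced variational autoencoder over ZINB likelihoods.

Architecture
------------
Encoder: a 1-D convolution slides along the (reordered) gene axis of each
cell's zero-filled count profile, a rectified-linear nonlinearity and a
fully connected hidden layer follow, and two linear heads emit the mean and
log-variance of a diagonal-Gaussian approximate posterior over a latent
vector ``z``. Decoder: a rectified-linear hidden layer followed by a linear
layer of width ``3G``, split into three blocks that become the ZINB
dropout probability (sigmoid), mean (softplus) and inverse dispersion
(softplus) for every gene of every cell.

Training minimizes

    L = L_ZINB + L_KL + lambda * L_MSE + lambda_reg * (lambda - 1)^2

where ``L_ZINB`` is the negative ZINB log-likelihood summed over all
entries, ``L_KL`` the KL divergence of the posterior from the standard
normal prior summed over cells, ``L_MSE`` a squared-error term between the
ZINB mean ``(1 - pi) mu`` and the observed counts on non-zero entries
only, and ``lambda`` a learnable scalar weight kept inside ``[0.5, 1.5]``.

All forward math is written with ``autograd.numpy``; gradients with
respect to the parameter dictionary come from reverse-mode autodiff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import autograd.numpy as anp
import numpy as np

from .zinb import ZINBParams, zinb_log_lik

# ---------------------------------------------------------------------------
# building blocks


def _relu(x):
    return anp.maximum(x, 0.0)


def _softplus(x):
    # log(1 + e^x), overflow-safe
    return anp.log1p(anp.exp(-anp.abs(x))) + anp.maximum(x, 0.0)


def _sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


@dataclass
class ConvSpec:
    """One shared 1-D convolution filter bank along the gene axis.

    ``weights`` has shape ``(out_channels, kernel_size)`` and ``bias``
    shape ``(out_channels,)``; the filters are shared across cells. Output
    length is ``L = floor((G - k) / s) + 1``.
    """

    kernel_size: int
    stride: int = 1
    out_channels: int = 1
    weights: np.ndarray | None = None
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.stride < 1 or self.out_channels < 1:
            raise ValueError("kernel_size, stride and out_channels must be >= 1")

    def out_length(self, n_genes: int) -> int:
        if n_genes < self.kernel_size:
            raise ValueError(
                f"kernel size {self.kernel_size} exceeds gene count {n_genes}"
            )
        return (n_genes - self.kernel_size) // self.stride + 1


def _window_index(n_genes: int, k: int, s: int) -> np.ndarray:
    length = (n_genes - k) // s + 1
    return (np.arange(length) * s)[:, None] + np.arange(k)[None, :]


def conv1d_forward(x, spec: ConvSpec, weights=None, bias=None):
    """Valid (no-padding) 1-D convolution ``H_j = sum_m w_m x_{js+m} + b``.

    ``x`` may be a single length-G vector or an ``(N, G)`` matrix; the
    result has shape ``(out_channels, L)`` resp. ``(N, out_channels, L)``.
    ``weights``/``bias`` override the ones stored on ``spec`` (used inside
    the differentiable training path).
    """
    w = spec.weights if weights is None else weights
    b = spec.bias if bias is None else bias
    if w is None or b is None:
        raise ValueError("ConvSpec carries no weights and none were supplied")
    squeeze = np.ndim(x) == 1
    x = anp.atleast_2d(x)
    g = x.shape[1]
    if g < spec.kernel_size:
        raise ValueError(f"gene vector of length {g} shorter than kernel {spec.kernel_size}")
    idx = _window_index(g, spec.kernel_size, spec.stride)
    windows = x[:, idx]  # (N, L, k)
    out = anp.einsum("nlk,ck->ncl", windows, anp.atleast_2d(w)) + anp.reshape(b, (-1, 1))
    return out[0] if squeeze else out


@dataclass
class LatentPosterior:
    """Per-cell diagonal-Gaussian posterior ``N(mu, diag(exp(log_var)))``."""

    mu: np.ndarray
    log_var: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.log_var = np.asarray(self.log_var, dtype=float)
        if self.mu.shape != self.log_var.shape:
            raise ValueError("mu and log_var must share one shape")
        if not (np.isfinite(self.mu).all() and np.isfinite(self.log_var).all()):
            raise ValueError("non-finite posterior parameters")

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(0.5 * self.log_var)


@dataclass
class LossBreakdown:
    """The four loss components plus their weighted total for one pass."""

    zinb: float
    kl: float
    mse: float
    lambda_weight: float
    penalty: float
    total: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        expected = self.zinb + self.kl + self.lambda_weight * self.mse + self.penalty
        if self.total is None:
            self.total = expected
        elif abs(self.total - expected) > 1e-9 * max(1.0, abs(expected)):
            raise ValueError("total inconsistent with components")


# ---------------------------------------------------------------------------
# architecture + parameters


@dataclass(frozen=True)
class Architecture:
    """Static shape information of one fitted network."""

    n_genes: int
    kernel_size: int
    stride: int
    out_channels: int
    hidden_dim: int
    latent_dim: int
    variant: str = "full"  # full | no_cnn | no_mse

    def __post_init__(self) -> None:
        if self.variant not in ("full", "no_cnn", "no_mse"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant != "no_cnn" and self.kernel_size > self.n_genes:
            raise ValueError("kernel size exceeds gene count")

    @property
    def uses_conv(self) -> bool:
        return self.variant != "no_cnn"

    @property
    def conv_out_length(self) -> int:
        return (self.n_genes - self.kernel_size) // self.stride + 1

    def conv_spec(self, params: dict | None = None) -> ConvSpec:
        w = b = None
        if params is not None:
            w, b = params.get("conv_w"), params.get("conv_b")
        return ConvSpec(self.kernel_size, self.stride, self.out_channels, w, b)


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def init_params(arch: Architecture, rng: np.random.Generator, lambda_init: float = 1.0) -> dict:
    """Seed-controlled fan-in-uniform initialization of all layers."""
    g, h, dz = arch.n_genes, arch.hidden_dim, arch.latent_dim
    p: dict[str, np.ndarray] = {}
    if arch.uses_conv:
        k, c = arch.kernel_size, arch.out_channels
        p["conv_w"] = _fan_in_uniform(rng, (c, k), k)
        p["conv_b"] = _fan_in_uniform(rng, (c,), k)
        enc_in = c * arch.conv_out_length
    else:
        enc_in = g
    p["fc_w"] = _fan_in_uniform(rng, (enc_in, h), enc_in)
    p["fc_b"] = _fan_in_uniform(rng, (h,), enc_in)
    p["mu_w"] = _fan_in_uniform(rng, (h, dz), h)
    p["mu_b"] = _fan_in_uniform(rng, (dz,), h)
    p["lv_w"] = _fan_in_uniform(rng, (h, dz), h)
    p["lv_b"] = _fan_in_uniform(rng, (dz,), h)
    p["dec_w"] = _fan_in_uniform(rng, (dz, h), dz)
    p["dec_b"] = _fan_in_uniform(rng, (h,), dz)
    p["out_w"] = _fan_in_uniform(rng, (h, 3 * g), h)
    p["out_b"] = _fan_in_uniform(rng, (3 * g,), h)
    p["lam"] = np.array(float(lambda_init))
    return p


# ---------------------------------------------------------------------------
# differentiable forward pass (params as an autograd dict container)


def encoder_forward(params: dict, X, arch: Architecture):
    """Raw encoder pass; returns ``(mu, log_var)`` as autograd arrays."""
    X = anp.asarray(X)
    if arch.uses_conv:
        idx = _window_index(arch.n_genes, arch.kernel_size, arch.stride)
        windows = X[:, idx]  # (N, L, k)
        conv = anp.einsum("nlk,ck->ncl", windows, params["conv_w"]) + anp.reshape(
            params["conv_b"], (-1, 1)
        )
        feat = anp.reshape(_relu(conv), (X.shape[0], -1))
    else:
        feat = X
    h = _relu(anp.dot(feat, params["fc_w"]) + params["fc_b"])
    mu = anp.dot(h, params["mu_w"]) + params["mu_b"]
    log_var = anp.dot(h, params["lv_w"]) + params["lv_b"]
    return mu, log_var


def decoder_forward(params: dict, Z, arch: Architecture):
    """Raw decoder pass; returns ``(pi, mu, theta)`` as autograd arrays."""
    h = _relu(anp.dot(Z, params["dec_w"]) + params["dec_b"])
    o = anp.dot(h, params["out_w"]) + params["out_b"]
    g = arch.n_genes
    pi = _sigmoid(o[:, :g])
    mu = _softplus(o[:, g : 2 * g])
    theta = _softplus(o[:, 2 * g :])
    return pi, mu, theta


def encode(params: dict, X, arch: Architecture) -> LatentPosterior:
    mu, log_var = encoder_forward(params, np.asarray(X, dtype=float), arch)
    return LatentPosterior(np.asarray(mu), np.asarray(log_var))


def reparameterize(post: LatentPosterior, eps: np.ndarray) -> np.ndarray:
    """``Z = mu + sigma * eps`` with ``sigma = exp(log_var / 2)``."""
    eps = np.asarray(eps, dtype=float)
    if eps.shape != post.mu.shape:
        raise ValueError("eps must match the posterior shape")
    return post.mu + post.sigma * eps


def decode(params: dict, Z, arch: Architecture) -> ZINBParams:
    pi, mu, theta = decoder_forward(params, np.asarray(Z, dtype=float), arch)
    # float saturation of sigmoid/softplus can touch the open boundaries
    pi = np.clip(np.asarray(pi), 1e-8, 1.0 - 1e-8)
    mu = np.maximum(np.asarray(mu), 1e-8)
    theta = np.maximum(np.asarray(theta), 1e-8)
    return ZINBParams(pi, mu, theta)


def kl_divergence(post: LatentPosterior | tuple) -> float:
    """KL(q || N(0, I)) summed over cells and latent dimensions."""
    if isinstance(post, LatentPosterior):
        mu, log_var = post.mu, post.log_var
    else:
        mu, log_var = post
    return 0.5 * anp.sum(mu**2 + anp.exp(log_var) - log_var - 1.0)


def masked_mse(X, pi, mu, omega=None):
    """Sum of squared errors between ``(1 - pi) mu`` and counts on Omega.

    Omega defaults to the non-zero (observed, non-dropout) entries of X.
    """
    X = anp.asarray(X)
    if omega is None:
        omega = np.asarray(X) > 0
    omega = np.asarray(omega, dtype=float)
    if omega.sum() == 0:
        warnings.warn("empty observed-entry set; MSE term is 0")
        return 0.0
    return anp.sum(omega * ((1.0 - pi) * mu - X) ** 2)


def loss_components(params: dict, X, eps, arch: Architecture, lambda_reg: float):
    """All loss pieces for one stochastic forward pass (autograd scalars)."""
    mu_z, log_var = encoder_forward(params, X, arch)
    z = mu_z + anp.exp(0.5 * log_var) * eps
    pi, mu, theta = decoder_forward(params, z, arch)
    zinb = -anp.sum(zinb_log_lik(anp.asarray(X), pi, mu, theta))
    kl = kl_divergence((mu_z, log_var))
    mse = masked_mse(X, pi, mu)
    lam = params["lam"]
    if arch.variant == "no_mse":
        total = zinb + kl
        return total, zinb, kl, mse, 0.0
    penalty = lambda_reg * (lam - 1.0) ** 2
    total = zinb + kl + lam * mse + penalty
    return total, zinb, kl, mse, penalty


def total_loss(X, p: ZINBParams, post: LatentPosterior, lambda_weight: float,
               lambda_reg: float, omega=None) -> LossBreakdown:
    """Composite loss from already-computed ZINB parameters and posterior."""
    x = np.asarray(X.values if hasattr(X, "values") else X, dtype=float)
    zinb = float(-np.sum(zinb_log_lik(x, p.pi, p.mu, p.theta)))
    kl = float(kl_divergence(post))
    mse = float(masked_mse(x, p.pi, p.mu, omega=omega))
    penalty = float(lambda_reg * (lambda_weight - 1.0) ** 2)
    return LossBreakdown(zinb=zinb, kl=kl, mse=mse,
                         lambda_weight=float(lambda_weight), penalty=penalty)
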