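"""Zero-Inflated Negative Binomial (ZINB) likelihood mathematics.

The ZINB distribution is a mixture of a point mass at zero, with weight
``pi`` (the dropout probability), and a Negative Binomial with mean ``mu``
and inverse dispersion ``theta``:

    P(X = 0)      = pi + (1 - pi) * NB(0; mu, theta)
    P(X = x), x>0 = (1 - pi) * NB(x; mu, theta)

with the NB pmf

    NB(x; mu, theta) = Gamma(x + theta) / (Gamma(theta) x!)
                       * (theta / (theta + mu))^theta
                       * (mu / (theta + mu))^x.

All functions are written with ``autograd.numpy`` so the same code serves
both as the public numerics API (on plain arrays) and as a differentiable
building block inside the training loss. Everything is computed in
log-space via log-gamma for stability; ``pi`` is clamped to
``[1e-8, 1 - 1e-8]`` and ``mu``, ``theta`` floored at ``1e-8`` before
evaluation, and the zero branch uses a log-sum-exp of
``{log pi, log(1-pi) + theta * (log theta - log(theta + mu))}``.
"""

from __future__ import annotations

import warnings

import autograd.numpy as anp
from autograd.scipy.special import gammaln

import numpy as np

from .io import CountMatrix

_EPS = 1e-8


def _validate_counts(x, allow_non_integer: bool = False) -> None:
    x = np.asarray(x)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    if not np.allclose(x, np.round(x)):
        if allow_non_integer:
            warnings.warn(
                "non-integer counts passed to a discrete likelihood; "
                "generalizing the pmf via log-gamma"
            )
        else:
            raise ValueError("counts must be integers (pass allow_non_integer=True to override)")


def nb_log_pmf(x, mu, theta):
    """Elementwise log NB pmf with mean ``mu`` and inverse dispersion ``theta``.

    Differentiable in ``mu`` and ``theta``; ``x`` is data.
    """
    mu = anp.maximum(mu, _EPS)
    theta = anp.maximum(theta, _EPS)
    return (
        gammaln(x + theta)
        - gammaln(theta)
        - gammaln(x + 1.0)
        + theta * (anp.log(theta) - anp.log(theta + mu))
        + x * (anp.log(mu) - anp.log(theta + mu))
    )


def zinb_log_lik(x, pi, mu, theta):
    """Elementwise ZINB log-likelihood ``l(x | pi, mu, theta)``.

    The zero branch ``log(pi + (1-pi) NB(0))`` is evaluated as a
    log-sum-exp so it stays finite for ``pi`` near 0 or 1.
    """
    pi = anp.clip(pi, _EPS, 1.0 - _EPS)
    mu = anp.maximum(mu, _EPS)
    theta = anp.maximum(theta, _EPS)
    log_nb_zero = theta * (anp.log(theta) - anp.log(theta + mu))
    a = anp.log(pi)
    b = anp.log1p(-pi) + log_nb_zero
    m = anp.maximum(a, b)
    zero_case = m + anp.log(anp.exp(a - m) + anp.exp(b - m))
    pos_case = anp.log1p(-pi) + nb_log_pmf(x, mu, theta)
    return anp.where(x < 0.5, zero_case, pos_case)


def zinb_nll(X, params, allow_non_integer: bool = False) -> float:
    """Negative sum of ZINB log-likelihoods over all cells and genes."""
    x = X.values if isinstance(X, CountMatrix) else np.asarray(X, dtype=float)
    _validate_counts(x, allow_non_integer=allow_non_integer)
    pi, mu, theta = params.pi, params.mu, params.theta
    if x.shape != np.shape(pi):
        raise ValueError(f"count matrix {x.shape} does not match parameters {np.shape(pi)}")
    return float(-np.sum(zinb_log_lik(x, pi, mu, theta)))


def zinb_mean(params) -> np.ndarray:
    """Expected value ``(1 - pi) * mu`` of the ZINB reconstruction."""
    return np.asarray((1.0 - params.pi) * params.mu)


class ZINBParams:
    """Per-entry ZINB parameter triplet ``(pi, mu, theta)``.

    ``pi`` lies strictly inside (0, 1) (decoder sigmoid), ``mu`` and
    ``theta`` are strictly positive (decoder softplus); all three share one
    cells × genes shape.
    """

    __slots__ = ("pi", "mu", "theta")

    def __init__(self, pi, mu, theta):
        pi = np.asarray(pi, dtype=float)
        mu = np.asarray(mu, dtype=float)
        theta = np.asarray(theta, dtype=float)
        if not (pi.shape == mu.shape == theta.shape):
            raise ValueError("pi, mu, theta must share one shape")
        if np.any(pi <= 0) or np.any(pi >= 1):
            raise ValueError("pi must lie strictly inside (0, 1)")
        if np.any(mu <= 0) or np.any(theta <= 0):
            raise ValueError("mu and theta must be strictly positive")
        self.pi, self.mu, self.theta = pi, mu, theta

    @property
    def shape(self):
        return self.pi.shape

    def mean(self) -> np.ndarray:
        return zinb_mean(self)
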