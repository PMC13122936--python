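"""Synthetic single-cell count data with known dropout ground truth.

The generator emulates the structure of droplet scRNA-seq counts needed by
the masking benchmark: log-normal per-gene base expression, cell groups
with fold-change differential genes, blocks of co-expressed genes driven
by a shared per-cell latent factor (so covariance-based gene reordering
has signal to find), and Negative Binomial sampling with a common inverse
dispersion. Dropout is then injected by zeroing a uniformly random,
exactly counted fraction of the non-zero entries, with the mask recorded,
so imputation error can be measured against known pre-dropout values at
missing rates anywhere in [0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CountMatrix


@dataclass
class SimConfig:
    """Generator settings.

    ``mean_log_mu``/``sd_log_mu`` give the natural-log-normal distribution
    of per-gene base means; ``de_prob`` of genes are differential, scaled
    by ``de_factor`` (up or down, equiprobably) in one random group;
    ``block_size`` consecutive genes share a per-cell log-normal factor of
    spread ``block_sigma`` (mean 1), planting co-expression; counts are
    NB with inverse dispersion ``theta_sim``. ``shuffle_genes`` permutes
    columns at the end so gene order carries no free information.
    """

    n_cells: int = 564
    n_genes: int = 2000
    n_groups: int = 4
    mean_log_mu: float = 0.0
    sd_log_mu: float = 1.0
    de_prob: float = 0.2
    de_factor: float = 3.0
    theta_sim: float = 2.0
    block_size: int = 20
    block_sigma: float = 0.6
    shuffle_genes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells, self.n_genes, self.n_groups) < 1:
            raise ValueError("n_cells, n_genes, n_groups must be positive")
        if not 0.0 <= self.de_prob <= 1.0:
            raise ValueError("de_prob must lie in [0, 1]")
        if self.theta_sim <= 0 or self.de_factor <= 0:
            raise ValueError("theta_sim and de_factor must be positive")


@dataclass
class DropoutMask:
    """Which entries of the complete matrix were zeroed, and at what rate."""

    mask: np.ndarray
    rate_requested: float
    rate_realized: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def simulate_counts(cfg: SimConfig, return_means: bool = False):
    """Draw a complete (pre-dropout) count matrix and cell group labels.

    With ``return_means=True`` the per-entry generative NB means are also
    returned (aligned with the, possibly shuffled, gene order of the
    matrix); they support oracle evaluations in benchmarks.
    """
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_cells, cfg.n_genes

    base_mu = np.exp(rng.normal(cfg.mean_log_mu, cfg.sd_log_mu, size=g))
    labels = rng.integers(0, cfg.n_groups, size=n)

    # group-differential genes: one random group, scaled up or down
    factors = np.ones((cfg.n_groups, g))
    de_genes = rng.random(g) < cfg.de_prob
    de_group = rng.integers(0, cfg.n_groups, size=g)
    up = rng.random(g) < 0.5
    scale = np.where(up, cfg.de_factor, 1.0 / cfg.de_factor)
    for grp in range(cfg.n_groups):
        sel = de_genes & (de_group == grp)
        factors[grp, sel] = scale[sel]
    mu = base_mu[None, :] * factors[labels]

    # planted co-expression blocks: consecutive genes share a cell factor
    if cfg.block_size > 1 and cfg.block_sigma > 0:
        n_blocks = int(np.ceil(g / cfg.block_size))
        # lognormal with mean exactly 1
        block_f = np.exp(
            rng.normal(-0.5 * cfg.block_sigma**2, cfg.block_sigma, size=(n, n_blocks))
        )
        block_of = np.repeat(np.arange(n_blocks), cfg.block_size)[:g]
        mu = mu * block_f[:, block_of]

    # NB(mean mu, inverse dispersion theta) via Gamma-Poisson mixture
    lam = rng.gamma(shape=cfg.theta_sim, scale=mu / cfg.theta_sim)
    counts = rng.poisson(lam).astype(float)

    if cfg.shuffle_genes:
        perm = rng.permutation(g)
        counts = counts[:, perm]
        mu = mu[:, perm]

    cm = CountMatrix(counts,
                     [f"cell{i}" for i in range(n)],
                     [f"gene{j}" for j in range(g)])
    if return_means:
        return cm, labels, mu
    return cm, labels


def apply_dropout(complete: CountMatrix, rate: float, seed: int = 0,
                  mode: str = "uniform", lambda_d: float = 0.05
                  ) -> tuple[CountMatrix, DropoutMask]:
    """Zero an exact random fraction of the non-zero entries.

    Exactly ``floor(rate * nnz)`` non-zero entries are masked, so the
    realized rate matches the request up to one entry's worth of rounding,
    and ``observed + masked originals`` reconstructs ``complete`` exactly.
    ``mode='uniform'`` (default) picks entries uniformly, giving a flat,
    interpretable missing rate; ``mode='expression'`` weights the pick by
    ``exp(-lambda_d * x^2)`` so low-expression entries drop out
    preferentially, closer to real capture noise.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if mode not in ("uniform", "expression"):
        raise ValueError("mode must be 'uniform' or 'expression'")
    rng = np.random.default_rng(seed)
    values = np.asarray(complete.values)
    nz_rows, nz_cols = np.nonzero(values)
    nnz = nz_rows.size
    n_mask = int(np.floor(rate * nnz))
    if mode == "expression" and n_mask > 0:
        w = np.exp(-lambda_d * values[nz_rows, nz_cols] ** 2)
        chosen = rng.choice(nnz, size=n_mask, replace=False, p=w / w.sum())
    else:
        chosen = rng.choice(nnz, size=n_mask, replace=False)
    mask = np.zeros(values.shape, dtype=bool)
    mask[nz_rows[chosen], nz_cols[chosen]] = True
    observed = values.copy()
    observed[mask] = 0
    obs = CountMatrix(observed, list(complete.cell_ids),
                      list(complete.gene_names),
                      is_transformed=complete.is_transformed)
    realized = n_mask / nnz if nnz else 0.0
    return obs, DropoutMask(mask, float(rate), float(realized))


@dataclass
class BenchmarkCase:
    """One masking level of the shared complete matrix."""

    rate: float
    observed: CountMatrix
    mask: DropoutMask
    complete: CountMatrix
    labels: np.ndarray
    true_means: np.ndarray | None = None  # generative NB means, for oracles


def make_benchmark_suite(cfg: SimConfig, rates) -> list[BenchmarkCase]:
    """One complete matrix, one graded-dropout variant per missing rate."""
    rates = [float(r) for r in rates]
    if not rates:
        raise ValueError("rates must be non-empty")
    complete, labels, means = simulate_counts(cfg, return_means=True)
    cases = []
    for i, rate in enumerate(rates):
        observed, mask = apply_dropout(complete, rate, seed=(cfg.seed * 1009 + i) % 2**31)
        cases.append(BenchmarkCase(rate, observed, mask, complete, labels, means))
    return cases
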