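"""End-to-end training: seeding, Adam optimization, adaptive MSE weight.

The training loop is: filter all-zero genes, reorder genes by co-expression,
then for a fixed number of epochs draw one reparameterization noise sample,
evaluate the composite loss, take an Adam step on every parameter (including
the scalar MSE weight ``lambda``), and project ``lambda`` back into its
allowed interval. Mini-batching kicks in only above 2048 cells; the
datasets this tool targets are small enough for full-batch gradients.

Ablation variants: ``no_cnn`` swaps the convolutional front end for a
fully connected layer applied directly to the gene vector; ``no_mse``
drops the weighted MSE term from the total (the component is still logged).
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import asdict, dataclass, field, replace
from io import BytesIO

import numpy as np
from autograd import grad

from . import model as M
from .io import CountMatrix, filter_zero_genes
from .reorder import GeneOrder, apply_order, compute_gene_order
from .zinb import ZINBParams


@dataclass
class TrainConfig:
    """All knobs of one training run.

    Defaults follow the published protocol: kernel 64, hidden width 128,
    latent width 64, 200 epochs of Adam at learning rate 1e-3, learnable
    MSE weight started at 1 and projected into [0.5, 1.5] with quadratic
    penalty 1e-3, imputation threshold tau = 1e-3.
    """

    kernel_size: int = 64
    stride: int = 1
    out_channels: int = 1
    hidden_dim: int = 128
    latent_dim: int = 64
    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int | None = None  # None: full batch up to 2048 cells, else 256
    lambda_init: float = 1.0
    lambda_bounds: tuple[float, float] = (0.5, 1.5)
    lambda_reg: float = 1e-3
    tau: float = 1e-3
    seed: int = 0
    variant: str = "full"
    reorder_on_log: bool = True

    def __post_init__(self) -> None:
        if self.variant not in ("full", "no_cnn", "no_mse"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if min(self.kernel_size, self.stride, self.hidden_dim, self.latent_dim,
               self.out_channels) < 1:
            raise ValueError("all architecture sizes must be positive")
        if self.learning_rate <= 0 or self.lambda_reg < 0 or self.tau < 0:
            raise ValueError("learning_rate must be > 0; lambda_reg, tau >= 0")
        lo, hi = self.lambda_bounds
        if not lo <= hi:
            raise ValueError("lambda_bounds must be ordered")


@dataclass
class TrainedModel:
    """A fitted network plus everything needed to impute with it."""

    params: dict
    arch: M.Architecture
    gene_order: GeneOrder
    kept_indices: np.ndarray
    input_gene_names: list[str]
    config: TrainConfig
    loss_history: list[M.LossBreakdown] = field(default_factory=list)

    def posterior_params(self, ordered_values: np.ndarray) -> ZINBParams:
        """Deterministic forward pass (eps = 0) on gene-ordered counts."""
        post = M.encode(self.params, ordered_values, self.arch)
        return M.decode(self.params, post.mu, self.arch)

    def save(self, path: str) -> None:
        save_model(self, path)


def set_global_seed(seed: int) -> np.random.Generator:
    """Seed numpy's legacy global RNG and return a fresh Generator.

    Every stochastic source in this package (initialization, noise draws,
    batching) flows from Generators derived from the configured seed, so
    identical seeds give bit-identical runs.
    """
    np.random.seed(seed % (2**32))
    return np.random.default_rng(seed)


class Adam:
    """Plain Adam over a dict of parameter arrays."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        corr1 = 1.0 - self.b1**self.t
        corr2 = 1.0 - self.b2**self.t
        for k in params:
            g = np.asarray(grads[k])
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            params[k] = params[k] - self.lr * (self.m[k] / corr1) / (
                np.sqrt(self.v[k] / corr2) + self.eps
            )


def _check_finite(breakdown: M.LossBreakdown, epoch: int) -> None:
    for name in ("zinb", "kl", "mse", "total"):
        if not np.isfinite(getattr(breakdown, name)):
            raise RuntimeError(
                f"non-finite loss component '{name}' at epoch {epoch}; aborting"
            )


def fit(m: CountMatrix, cfg: TrainConfig) -> TrainedModel:
    """Train on a count matrix and return the fitted model.

    All-zero genes are dropped (idempotent if already filtered), genes are
    reordered by co-expression, and the network is trained full-batch (or
    in shuffled mini-batches of 256 above 2048 cells).
    """
    if cfg.epochs < 1:
        raise ValueError("epochs must be >= 1 (nothing would be trained)")
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells to fit")
    rng = set_global_seed(cfg.seed)

    filtered, kept = filter_zero_genes(m)
    order = compute_gene_order(filtered, use_log=cfg.reorder_on_log)
    ordered = apply_order(filtered, order)
    X = np.asarray(ordered.values, dtype=float)
    n, g = X.shape

    kernel = cfg.kernel_size
    if cfg.variant != "no_cnn" and kernel > g:
        warnings.warn(f"kernel {kernel} exceeds {g} genes; shrinking to {g}")
        kernel = g
    arch = M.Architecture(
        n_genes=g, kernel_size=kernel, stride=cfg.stride,
        out_channels=cfg.out_channels, hidden_dim=cfg.hidden_dim,
        latent_dim=cfg.latent_dim, variant=cfg.variant,
    )
    params = M.init_params(arch, rng, lambda_init=cfg.lambda_init)
    opt = Adam(params, cfg.learning_rate)
    lo, hi = cfg.lambda_bounds

    batch = cfg.batch_size
    if batch is None:
        batch = n if n <= 2048 else 256
    batch = min(batch, n)

    def objective(p, xb, eb):
        return M.loss_components(p, xb, eb, arch, cfg.lambda_reg)[0]

    dloss = grad(objective)

    history: list[M.LossBreakdown] = []
    for epoch in range(cfg.epochs):
        idx = np.arange(n) if batch == n else rng.permutation(n)
        comp = np.zeros(4)  # zinb, kl, mse, penalty sums over batches
        lam_now = float(params["lam"])
        for start in range(0, n, batch):
            rows = idx[start : start + batch]
            xb = X[rows]
            eb = rng.standard_normal((len(rows), arch.latent_dim))
            total, zinb, kl, mse, pen = M.loss_components(
                params, xb, eb, arch, cfg.lambda_reg
            )
            comp += [float(zinb), float(kl), float(mse), float(pen)]
            grads = dloss(params, xb, eb)
            opt.step(params, grads)
            if cfg.variant == "no_mse":
                params["lam"] = np.array(lam_now)  # weight plays no role
            else:
                params["lam"] = np.clip(params["lam"], lo, hi)
        lam_logged = 0.0 if cfg.variant == "no_mse" else lam_now
        breakdown = M.LossBreakdown(
            zinb=comp[0], kl=comp[1], mse=comp[2],
            lambda_weight=lam_logged, penalty=comp[3],
        )
        _check_finite(breakdown, epoch)
        history.append(breakdown)

    return TrainedModel(
        params=params, arch=arch, gene_order=order, kept_indices=kept,
        input_gene_names=list(m.gene_names), config=cfg, loss_history=history,
    )


def run_multi_seed(m: CountMatrix, cfg: TrainConfig, seeds: list[int]) -> list[TrainedModel]:
    """Independent fits, one per seed; reporting averages over them."""
    if not seeds:
        raise ValueError("seeds must be non-empty")
    return [fit(m, replace(cfg, seed=int(s))) for s in seeds]


# ---------------------------------------------------------------------------
# persistence: one zip archive of parameter arrays + JSON metadata


def save_model(model: TrainedModel, path: str) -> None:
    meta = {
        "arch": asdict(model.arch),
        "config": asdict(model.config),
        "permutation": model.gene_order.permutation.tolist(),
        "kept_indices": np.asarray(model.kept_indices).tolist(),
        "input_gene_names": model.input_gene_names,
        "loss_history": [asdict(h) for h in model.loss_history],
    }
    buf = BytesIO()
    np.savez(buf, **{f"param_{k}": v for k, v in model.params.items()})
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("params.npz", buf.getvalue())
        zf.writestr("meta.json", json.dumps(meta))


def load_model(path: str) -> TrainedModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        with np.load(BytesIO(zf.read("params.npz"))) as npz:
            params = {k[len("param_"):]: npz[k].copy() for k in npz.files}
    cfg_d = meta["config"]
    cfg_d["lambda_bounds"] = tuple(cfg_d["lambda_bounds"])
    return TrainedModel(
        params=params,
        arch=M.Architecture(**meta["arch"]),
        gene_order=GeneOrder(np.asarray(meta["permutation"], dtype=int)),
        kept_indices=np.asarray(meta["kept_indices"], dtype=int),
        input_gene_names=list(meta["input_gene_names"]),
        config=TrainConfig(**cfg_d),
        loss_history=[M.LossBreakdown(**h) for h in meta["loss_history"]],
    )
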