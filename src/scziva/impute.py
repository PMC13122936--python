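"""Probability-guided selective imputation.

Only zero entries whose estimated dropout probability exceeds a threshold
``tau`` are replaced, by the ZINB mean ``(1 - pi) * mu``; every non-zero
entry and every zero deemed biologically plausible is left untouched:

    Xhat_ij = (1 - pi_ij) * mu_ij   if X_ij = 0 and pi_ij > tau
    Xhat_ij = X_ij                  otherwise.

Inference is deterministic: the latent code is the posterior mean
(reparameterization noise set to zero), so a fixed model and threshold
always give the same imputed matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountMatrix
from .reorder import restore_order
from .train import TrainedModel
from .zinb import ZINBParams


@dataclass
class ImputedMatrix:
    """An imputed matrix plus the record of which entries were filled in."""

    values: np.ndarray
    imputed_mask: np.ndarray
    tau: float
    cell_ids: list[str]
    gene_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.imputed_mask = np.asarray(self.imputed_mask, dtype=bool)
        if self.values.shape != self.imputed_mask.shape:
            raise ValueError("values and imputed_mask must share one shape")

    @property
    def n_imputed(self) -> int:
        return int(self.imputed_mask.sum())

    def as_count_matrix(self) -> CountMatrix:
        """View as a (transformed-flagged) CountMatrix for downstream code."""
        return CountMatrix(self.values, list(self.cell_ids),
                          list(self.gene_names), is_transformed=True)


def _ordered_zinb(model: TrainedModel, m: CountMatrix):
    """Validate genes against the model and run the deterministic forward."""
    if list(m.gene_names) != list(model.input_gene_names):
        raise ValueError(
            "gene names of the input do not match the model's training genes"
        )
    filtered = m.values[:, model.kept_indices]
    ordered = filtered[:, model.gene_order.permutation]
    params = model.posterior_params(np.asarray(ordered, dtype=float))
    return ordered, params


def impute(model: TrainedModel, m: CountMatrix, tau: float | None = None) -> ImputedMatrix:
    """Selectively impute zeros of ``m`` with the fitted model.

    ``tau`` defaults to the threshold stored in the model's config (1e-3).
    The result is returned in the caller's original gene order; genes that
    were all-zero at training time pass through unchanged.
    """
    if tau is None:
        tau = model.config.tau
    if tau < 0:
        raise ValueError("tau must be non-negative")
    ordered, p = _ordered_zinb(model, m)
    zmean = (1.0 - p.pi) * p.mu
    fire = (np.asarray(ordered) == 0) & (p.pi > tau)
    xhat_ordered = np.where(fire, zmean, ordered)

    # back to the caller's gene order, then scatter into the full gene set
    inv = model.gene_order.inverse
    xhat_filtered = xhat_ordered[:, inv]
    fire_filtered = fire[:, inv]
    values = np.asarray(m.values, dtype=float).copy()
    mask = np.zeros(values.shape, dtype=bool)
    values[:, model.kept_indices] = xhat_filtered
    mask[:, model.kept_indices] = fire_filtered
    return ImputedMatrix(values, mask, float(tau),
                         list(m.cell_ids), list(m.gene_names))


def dropout_probabilities(model: TrainedModel, m: CountMatrix) -> np.ndarray:
    """Estimated dropout probabilities pi in the caller's gene order.

    Genes dropped at training time (all-zero columns) get pi = 0.
    """
    _, p = _ordered_zinb(model, m)
    pi_full = np.zeros(m.values.shape)
    pi_full[:, model.kept_indices] = p.pi[:, model.gene_order.inverse]
    return pi_full


def tau_sweep(model: TrainedModel, m: CountMatrix, taus, mask=None,
              complete: CountMatrix | None = None) -> pd.DataFrame:
    """Imputed-entry counts (and optional masked-entry metrics) per tau.

    ``taus`` must be sorted ascending; the imputed count is non-increasing
    along the sweep. With a ground-truth ``complete`` matrix and its
    ``DropoutMask``, masked-entry RMSE/MAE/PCC are reported per threshold.
    """
    taus = [float(t) for t in taus]
    if not taus:
        raise ValueError("taus must be non-empty")
    if any(b < a for a, b in zip(taus, taus[1:])):
        raise ValueError("taus must be sorted ascending")
    rows = []
    for t in taus:
        imp = impute(model, m, tau=t)
        row = {"tau": t, "n_imputed": imp.n_imputed}
        if mask is not None and complete is not None:
            from .evaluate import compute_metrics

            rep = compute_metrics(complete, imp, scope="masked_only", mask=mask)
            row.update(rmse=rep.rmse, mae=rep.mae, pcc=rep.pcc)
        rows.append(row)
    return pd.DataFrame(rows)
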