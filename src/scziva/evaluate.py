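"""Imputation-quality metrics and downstream-analysis evaluation.

Imputation accuracy is scored by RMSE, MAE and the grand-mean-centred
Pearson correlation between the imputed and ground-truth matrices, either
over all entries or restricted to the positions where dropout was
artificially injected (the scope that ground truth actually certifies).
Both matrices are placed on the same log scale first: per-cell median
library scale factors computed from the truth matrix are applied to both,
followed by log2(1 + x). Downstream support is measured by PCA + k-means
clustering agreement (ARI/NMI), Kendall rank correlation for orderings,
and top-N differentially-expressed-gene overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .io import CountMatrix, library_scale_factors, log_normalize


def _values(x) -> np.ndarray:
    if hasattr(x, "values"):
        return np.asarray(x.values, dtype=float)
    return np.asarray(x, dtype=float)


def _is_transformed(x) -> bool:
    return bool(getattr(x, "is_transformed", False))


@dataclass
class MetricsReport:
    rmse: float
    mae: float
    pcc: float
    scope: str
    n_entries: int


def compute_metrics(truth, imputed, scope: str = "masked_only", mask=None,
                    log_scale: bool = True) -> MetricsReport:
    """RMSE / MAE / grand-mean-centred PCC between truth and imputation.

    ``scope='masked_only'`` (requires ``mask``) restricts to entries where
    dropout was injected; ``'all_entries'`` uses the whole matrix. With
    ``log_scale`` both matrices are library-scaled (factors from ``truth``)
    and log2(1+x)-transformed before comparison; raw values are compared
    if the inputs are already flagged transformed or ``log_scale=False``.
    """
    xt = _values(truth)
    xi = _values(imputed)
    if xt.shape != xi.shape:
        raise ValueError(f"shape mismatch: truth {xt.shape}, imputed {xi.shape}")
    if scope not in ("all_entries", "masked_only"):
        raise ValueError("scope must be 'all_entries' or 'masked_only'")
    if log_scale and not _is_transformed(truth):
        factors = library_scale_factors(xt)
        xt = np.log2(1.0 + xt * factors[:, None])
        xi = np.log2(1.0 + xi * factors[:, None])
    if scope == "masked_only":
        if mask is None:
            raise ValueError("masked_only scope requires a DropoutMask")
        sel = np.asarray(getattr(mask, "mask", mask), dtype=bool)
        if sel.shape != xt.shape:
            raise ValueError("mask shape does not match matrices")
        a, b = xt[sel], xi[sel]
    else:
        a, b = xt.ravel(), xi.ravel()
    n = a.size
    if n == 0:
        raise ValueError("no entries in scope")
    diff = a - b
    rmse = float(np.sqrt(np.mean(diff**2)))
    mae = float(np.mean(np.abs(diff)))
    ca, cb = a - a.mean(), b - b.mean()
    denom = np.sqrt(np.sum(ca**2)) * np.sqrt(np.sum(cb**2))
    if denom == 0:
        warnings.warn("constant matrix in scope; PCC undefined (NaN)")
        pcc = float("nan")
    else:
        pcc = float(np.sum(ca * cb) / denom)
    return MetricsReport(rmse=rmse, mae=mae, pcc=pcc, scope=scope, n_entries=n)


def clustering_eval(m: CountMatrix, true_labels, n_components: int = 50,
                    k: int | None = None, seed: int = 0) -> tuple[float, float]:
    """PCA + seeded k-means agreement (ARI, NMI) with reference labels.

    ``k`` defaults to the number of distinct reference labels, mirroring
    the convention of evaluating on annotated datasets.
    """
    true_labels = np.asarray(true_labels)
    if len(true_labels) != m.n_cells:
        raise ValueError("one label per cell required")
    if k is None:
        k = len(np.unique(true_labels))
    if k < 2:
        raise ValueError("k must be at least 2")
    data = m if m.is_transformed else log_normalize(m)
    x = np.asarray(data.values, dtype=float)
    n_comp = min(n_components, x.shape[1] - 1, x.shape[0] - 1)
    if n_comp >= 1:
        x = PCA(n_components=n_comp, random_state=seed).fit_transform(x)
    pred = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(x)
    ari = adjusted_rand_score(true_labels, pred)
    nmi = normalized_mutual_info_score(true_labels, pred)
    return float(ari), float(nmi)


def kendall_tau(pseudo_order, true_order) -> float:
    """Kendall tau-b rank correlation between two orderings."""
    a, b = np.asarray(pseudo_order), np.asarray(true_order)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("orderings must share a length of at least 2")
    return float(scipy.stats.kendalltau(a, b, variant="b").statistic)


def overlap_proportion(list_a, list_b, top_n: int) -> float:
    """|top_n(a) ∩ top_n(b)| / top_n for two ranked gene lists."""
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if top_n > len(list_a) or top_n > len(list_b):
        raise ValueError("top_n exceeds a list length")
    return len(set(list_a[:top_n]) & set(list_b[:top_n])) / top_n


def rank_genes_wilcoxon(m: CountMatrix, labels, group_a, group_b) -> list[str]:
    """Genes ranked by Wilcoxon rank-sum p-value between two cell groups."""
    labels = np.asarray(labels)
    sel_a, sel_b = labels == group_a, labels == group_b
    if sel_a.sum() < 2 or sel_b.sum() < 2:
        raise ValueError("each group needs at least 2 cells")
    data = m if m.is_transformed else log_normalize(m)
    x = np.asarray(data.values, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stats = scipy.stats.ranksums(x[sel_a], x[sel_b], axis=0)
    pvals = np.nan_to_num(stats.pvalue, nan=1.0)
    order = np.argsort(pvals, kind="stable")
    return [m.gene_names[j] for j in order]


def benchmark_report(entries, out_path: str | None = None) -> pd.DataFrame:
    """Tidy per-rate, per-seed metric table with per-rate seed means.

    ``entries`` is an iterable of ``(rate, seed, MetricsReport)``. Mean
    rows carry ``seed='mean'``. Written as TSV when ``out_path`` is given.
    """
    rows = [
        {"rate": float(r), "seed": str(s), "rmse": rep.rmse,
         "mae": rep.mae, "pcc": rep.pcc, "n_entries": rep.n_entries}
        for r, s, rep in entries
    ]
    if not rows:
        raise ValueError("no benchmark entries supplied")
    df = pd.DataFrame(rows)
    means = (
        df.groupby("rate", as_index=False)[["rmse", "mae", "pcc"]]
        .mean()
        .assign(seed="mean", n_entries=-1)
    )
    out = pd.concat([df, means], ignore_index=True).sort_values(
        ["rate", "seed"], ignore_index=True
    )
    if out_path is not None:
        out.to_csv(out_path, sep="\t", index=False)
    return out
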