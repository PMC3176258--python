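"""PCA with held-out projection, heatmap exports and trajectory plots.

Figures are exported as data files (TSV of coordinates and row orders) so
that downstream checks assert on numbers, with optional rendered images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .dataio import Dataset


@dataclass
class PCAModel:
    """A PCA fitted on one set of samples, applicable to held-out samples."""

    gene_ids: list[str]
    mean: np.ndarray
    scale: np.ndarray | None
    components: np.ndarray  # n_components x n_genes, orthonormal rows
    explained_variance_ratio: np.ndarray


def fit_pca(
    ds: Dataset,
    genes: Sequence[str] | None = None,
    n_components: int = 3,
    scale_genes: bool = False,
) -> PCAModel:
    """PCA of samples in the space of ``genes`` (default: all genes).

    Genes are centered (and optionally unit-variance scaled) with the fitting
    samples' statistics; components come from the SVD of the centered matrix.
    Sign convention: each component's largest-magnitude loading is positive.
    """
    genes = list(genes) if genes is not None else ds.gene_ids
    missing = [g for g in genes if g not in ds.expr.index]
    if missing:
        raise KeyError(f"genes not in dataset: {missing[:5]}")
    X = ds.expr.loc[genes].to_numpy().T  # samples x genes
    n, p = X.shape
    if n_components > min(p, n - 1):
        raise ValueError(
            f"n_components={n_components} exceeds min(#genes, #samples-1)="
            f"{min(p, n - 1)}"
        )
    mean = X.mean(axis=0)
    scale = None
    Xc = X - mean
    if scale_genes:
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0
        Xc = Xc / scale
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = (s**2).sum()
    if total_var == 0 or (s[:n_components] <= 1e-12 * s[0]).any():
        raise ValueError(f"data rank is below n_components={n_components}")
    comps = vt[:n_components]
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(comps.shape[0]):
        j = int(np.argmax(np.abs(comps[k])))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
    evr = (s[:n_components] ** 2) / total_var
    return PCAModel(
        gene_ids=genes, mean=mean, scale=scale, components=comps,
        explained_variance_ratio=evr,
    )


def project(model: PCAModel, ds: Dataset) -> pd.DataFrame:
    """Sample scores of ``ds`` in the model's component space.

    Held-out samples are centered with the *model's* means (and scale) and
    projected on its loadings; projecting the fitting samples reproduces
    their fit scores.
    """
    missing = [g for g in model.gene_ids if g not in ds.expr.index]
    if missing:
        raise KeyError(f"genes missing from dataset: {missing[:5]}")
    X = ds.expr.loc[model.gene_ids].to_numpy().T
    Xc = X - model.mean
    if model.scale is not None:
        Xc = Xc / model.scale
    scores = Xc @ model.components.T
    cols = [f"PC{k + 1}" for k in range(model.components.shape[0])]
    return pd.DataFrame(scores, index=ds.sample_ids, columns=cols)


def zscore_rows(expr: pd.DataFrame) -> pd.DataFrame:
    """Scale each gene row to mean 0, population (divide-by-n) sd 1.

    Constant rows become all zeros, with a warning.
    """
    X = expr.to_numpy(dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # population sd
    flat = (sd == 0.0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant rows z-scored to zeros", stacklevel=2
        )
    sd[sd == 0.0] = 1.0
    return pd.DataFrame((X - mean) / sd, index=expr.index, columns=expr.columns)


def hierarchical_order(
    expr: pd.DataFrame,
    method: Literal["average", "complete"] = "average",
    metric: Literal["euclidean", "correlation"] = "euclidean",
) -> list[str]:
    """Leaf order of agglomerative clustering of z-scored gene rows."""
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes to cluster")
    Z = zscore_rows(expr).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-row warning already emitted
        dists = pdist(Z, metric=metric)
    dists = np.nan_to_num(dists, nan=0.0)
    tree = linkage(dists, method=method)
    order = leaves_list(tree)
    return [expr.index[i] for i in order]


def heatmap_export(ds: Dataset, genes: Sequence[str], path,
                   method: Literal["average", "complete"] = "average") -> pd.DataFrame:
    """Z-scored, cluster-ordered signature matrix written as TSV."""
    sub = ds.expr.loc[list(genes)]
    z = zscore_rows(sub)
    order = hierarchical_order(sub, method=method)
    out = z.loc[order]
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")
    return out


def pca_scores_export(model: PCAModel, ds: Dataset, path) -> pd.DataFrame:
    """Sample scores TSV with class and potency annotation columns."""
    scores = project(model, ds)
    scores["class_label"] = ds.annot["class_label"].to_numpy()
    scores["potency"] = ds.annot["potency"].to_numpy()
    scores.index.name = "sample_id"
    scores.to_csv(path, sep="\t", float_format="%.6g")
    return scores


def plot_kld_trace(trace, path) -> None:
    """Render the elimination KLD trajectory with the breakpoint marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traj = trace.kld_trajectory()
    steps = np.arange(1, len(traj) + 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(steps, traj, lw=1)
    ax.axvline(trace.breakpoint_step, color="red", ls="--",
               label=f"breakpoint (n={len(trace.signature)})")
    ax.set_xlabel("analytes eliminated")
    ax.set_ylabel("KLD")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_roc(rocs, path) -> None:
    """Render one or more ROC curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for i, roc in enumerate(rocs):
        ax.plot(roc.fpr, roc.tpr, lw=1, alpha=0.7,
                label=f"iter {i} (AUC {roc.auc:.2f})" if len(rocs) <= 8 else None)
    ax.plot([0, 1], [0, 1], color="grey", ls=":")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    if len(rocs) <= 8:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
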