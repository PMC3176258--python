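"""Per-transcript ANOVA filtering with FDR correction and candidate selection.

Two filters are provided: a two-group one-way ANOVA comparing sensitizing vs
non-sensitizing chemicals (equivalent to a pooled-variance t test squared),
and a multi-group one-way ANOVA across every individual stimulation
(compound), with vehicle controls as their own groups.  Raw p-values drive
candidate selection; Benjamini-Hochberg q-values are reported alongside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import CLASS_CONTROL, CLASS_NONSENSITIZER, CLASS_SENSITIZER, Dataset

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300  # keep p-values inside (0, 1]


@dataclass
class CandidateSet:
    """Genes passing the ANOVA filter, ordered by ascending p (ties by id)."""

    gene_ids: list[str]
    threshold: float
    comparison: Literal["two_group", "multi_group"]

    def __len__(self) -> int:
        return len(self.gene_ids)


def _oneway_f_pvalues(X: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Vectorized one-way fixed-effects ANOVA per row of X (genes x samples).

    ``groups`` is an integer coding of sample groups.  Returns the p-value
    from F(k-1, n-k).  Rows with zero between- and within-group variation
    get p = 1.
    """
    n = X.shape[1]
    labels = np.unique(groups)
    k = labels.size
    grand = X.mean(axis=1, keepdims=True)
    ssb = np.zeros(X.shape[0])
    ssw = np.zeros(X.shape[0])
    for g in labels:
        sel = X[:, groups == g]
        m = sel.mean(axis=1, keepdims=True)
        ssb += sel.shape[1] * (m - grand).ravel() ** 2
        ssw += ((sel - m) ** 2).sum(axis=1)
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / (ssw / df2)
    p = stats.f.sf(f, df1, df2)
    p[(ssw == 0) & (ssb == 0)] = 1.0  # totally flat gene: no evidence
    p[(ssw == 0) & (ssb > 0)] = _P_FLOOR  # perfect separation, F = inf
    return np.clip(p, _P_FLOOR, 1.0)


def _chemical_mask(ds: Dataset, include_controls_as_nonsens: bool) -> pd.Series:
    labels = ds.annot["class_label"]
    if include_controls_as_nonsens:
        return labels.isin([CLASS_SENSITIZER, CLASS_NONSENSITIZER, CLASS_CONTROL])
    return labels.isin([CLASS_SENSITIZER, CLASS_NONSENSITIZER])


def anova_two_group(
    ds: Dataset, include_controls_as_nonsens: bool = False
) -> pd.Series:
    """Per-gene one-way ANOVA p comparing sensitizers vs non-sensitizers.

    Vehicle controls are excluded by default; with
    ``include_controls_as_nonsens`` they join the non-sensitizer group.
    For two groups the F statistic equals the squared pooled-variance t.
    """
    mask = _chemical_mask(ds, include_controls_as_nonsens)
    sub = ds.annot.loc[mask[mask].index]
    y = (sub["class_label"] == CLASS_SENSITIZER).to_numpy().astype(int)
    for cls, cnt in zip(*np.unique(y, return_counts=True)):
        if cnt < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = ds.expr[sub.index].to_numpy()
    p = _oneway_f_pvalues(X, y)
    return pd.Series(p, index=ds.expr.index, name="p_two_group")


def anova_multi_group(ds: Dataset) -> pd.Series:
    """Per-gene one-way ANOVA p across all compound groups.

    Every compound (and each vehicle-control token) is its own group; each
    group needs >= 2 samples.
    """
    codes, uniques = pd.factorize(ds.annot["compound_id"])
    for i, cnt in enumerate(np.bincount(codes)):
        if cnt < 2:
            raise ValueError(f"compound group {uniques[i]!r} has fewer than 2 samples")
    if len(uniques) < 2:
        raise ValueError("need at least 2 compound groups")
    X = ds.expr.to_numpy()
    p = _oneway_f_pvalues(X, codes)
    return pd.Series(p, index=ds.expr.index, name="p_multi_group")


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_gene_stats(
    ds: Dataset, include_controls_as_nonsens: bool = False
) -> pd.DataFrame:
    """Both ANOVA filters plus BH q-values, one row per gene."""
    p2 = anova_two_group(ds, include_controls_as_nonsens)
    pm = anova_multi_group(ds)
    stats_df = pd.DataFrame(
        {
            "p_two_group": p2,
            "q_two_group": bh_fdr(p2.to_numpy()),
            "p_multi_group": pm,
            "q_multi_group": bh_fdr(pm.to_numpy()),
        }
    )
    stats_df.index.name = "gene_id"
    return stats_df


def select_candidates(
    gene_stats: pd.DataFrame,
    comparison: Literal["two_group", "multi_group"] = "two_group",
    threshold: float | None = None,
    top_k: int | None = None,
    use_q: bool = False,
) -> CandidateSet:
    """Select the candidate analyte set by p-value threshold or size.

    Exactly one of ``threshold`` (keep p <= threshold) and ``top_k`` (keep
    the k smallest p) must be given.  Genes are ordered by ascending p with
    deterministic gene-id tie-break.  An empty selection warns but is not an
    error.
    """
    if (threshold is None) == (top_k is None):
        raise ValueError("give exactly one of threshold or top_k")
    col = ("q_" if use_q else "p_") + comparison
    if col not in gene_stats.columns:
        raise ValueError(f"gene stats lack column {col!r}")
    ordered = (
        gene_stats[[col]]
        .rename_axis("gene_id")
        .reset_index()
        .sort_values([col, "gene_id"], kind="mergesort")
        .set_index("gene_id")
    )
    if threshold is not None:
        if not 0 < threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        chosen = ordered.index[ordered[col] <= threshold].tolist()
        eff_threshold = threshold
    else:
        if top_k < 0:
            raise ValueError("top_k must be >= 0")
        chosen = ordered.index[:top_k].tolist()
        eff_threshold = float(ordered[col].iloc[top_k - 1]) if chosen else 0.0
    if not chosen:
        warnings.warn("candidate selection produced an empty set", stacklevel=2)
    logger.info("selected %d candidate analytes (%s)", len(chosen), col)
    return CandidateSet(gene_ids=chosen, threshold=eff_threshold, comparison=comparison)


def write_gene_stats(gene_stats: pd.DataFrame, path) -> None:
    gene_stats.to_csv(path, sep="\t", float_format="%.6g")


def write_candidates(cands: CandidateSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# comparison: {cands.comparison}\n")
        fh.write(f"# threshold: {cands.threshold:.6g}\n")
        fh.write("gene_id\n")
        for g in cands.gene_ids:
            fh.write(g + "\n")
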