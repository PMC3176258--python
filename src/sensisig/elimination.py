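"""Backward elimination of analytes scored by the Kullback-Leibler divergence
of leave-one-out cross-validated SVM predictions.

At each step with N analytes remaining, every analyte is left out in turn and
a linear SVM is evaluated by LOOCV on the remaining N-1; the divergence
between the true class labels and the calibrated cross-validated class
probabilities is recorded, and the analyte whose removal yields the smallest
divergence — the one contributing the least non-redundant information — is
eliminated.  The trajectory of divergences typically falls while redundant
analytes are removed and rises again once informative ones start to go; the
step achieving the global minimum is the *breakpoint*, and the analytes still
in play there form the signature.

The default divergence is the mean KL divergence between the one-hot
true-label distribution and the calibrated LOOCV probability estimate, which
reduces to the mean negative log predicted probability of the true class
(natural log).  An alternative scoring — the symmetrized KL divergence
between class-conditional Gaussians fitted to the LOOCV decision values,
maximized rather than minimized — is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .dataio import CLASS_SENSITIZER, Dataset
from .diffexpr import CandidateSet
from .svm import DEFAULT_COST, PROB_CLIP, fit_platt, loocv_decision_values, sigmoid_probability

logger = logging.getLogger(__name__)

KldVariant = Literal["crossentropy", "gaussian"]


class EliminationStep(NamedTuple):
    eliminated_gene: str
    kld_after: float
    n_remaining: int


@dataclass
class EliminationTrace:
    """Record of a backward-elimination run, including the breakpoint."""

    candidates: list[str]
    steps: list[EliminationStep]
    initial_kld: float
    variant: KldVariant = "crossentropy"
    breakpoint_step: int = 0
    signature: list[str] = field(default_factory=list)

    def kld_trajectory(self) -> np.ndarray:
        return np.array([s.kld_after for s in self.steps])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.steps, columns=["eliminated_gene", "kld_after", "n_remaining"])
        df.insert(0, "step", np.arange(1, len(df) + 1))
        return df


def _chemical_xy(ds: Dataset, genes: Sequence[str]) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Expression (samples x genes) and +/-1 labels for chemical samples only."""
    sub = ds.annot[ds.annot["class_label"] != "vehicle_control"]
    missing = [g for g in genes if g not in ds.expr.index]
    if missing:
        raise KeyError(f"genes not in dataset: {missing[:5]}")
    X = ds.expr.loc[list(genes), sub.index].to_numpy().T
    y = np.where(sub["class_label"] == CLASS_SENSITIZER, 1.0, -1.0)
    return np.ascontiguousarray(X), y, sub


def kld(probs: Sequence[float]) -> float:
    """Mean KL divergence of one-hot truths from predicted true-class
    probabilities: -(1/S) * sum(ln p_true)."""
    p = np.asarray(probs, dtype=float)
    if p.size == 0:
        raise ValueError("kld of empty input")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    return float(-np.mean(np.log(p)))


def _gaussian_symkld(d: np.ndarray, y: np.ndarray) -> float:
    """Symmetrized KL divergence between class-conditional Gaussians of d."""
    a, b = d[y > 0], d[y < 0]
    ma, mb = a.mean(), b.mean()
    va = max(a.var(), 1e-12)
    vb = max(b.var(), 1e-12)
    return float(0.5 * (va / vb + vb / va - 2.0) / 2.0
                 + 0.5 * (ma - mb) ** 2 * (1.0 / va + 1.0 / vb) / 2.0)


def _score(d: np.ndarray, y: np.ndarray, variant: KldVariant) -> float:
    if variant == "crossentropy":
        A, B = fit_platt(d, y)
        p_pos = sigmoid_probability(d, A, B)
        p_true = np.where(y > 0, p_pos, 1.0 - p_pos)
        return kld(np.clip(p_true, PROB_CLIP, 1 - PROB_CLIP))
    if variant == "gaussian":
        return _gaussian_symkld(d, y)
    raise ValueError(f"unknown kld variant {variant!r}")


def loocv_probabilities(
    ds: Dataset,
    genes: Sequence[str],
    cost: float = DEFAULT_COST,
    level: Literal["sample", "compound"] = "sample",
    tol: float = 1e-3,
) -> pd.Series:
    """Per-sample LOOCV probability of the sample's true class.

    Each chemical sample is predicted by an SVM trained on all the others
    (``level='compound'`` leaves out whole compounds, replicates together);
    a single sigmoid calibration is then fitted on the collected out-of-fold
    decision values and label pairs.  Probabilities are clipped to
    [1e-6, 1-1e-6].
    """
    X, y, sub = _chemical_xy(ds, genes)
    groups = sub["compound_id"].to_numpy() if level == "compound" else None
    d = loocv_decision_values(X, y, cost=cost, tol=tol, groups=groups)
    A, B = fit_platt(d, y)
    p_pos = sigmoid_probability(d, A, B)
    p_true = np.where(y > 0, p_pos, 1.0 - p_pos)
    return pd.Series(np.clip(p_true, PROB_CLIP, 1 - PROB_CLIP), index=sub.index)


def backward_eliminate(
    ds: Dataset,
    candidates: CandidateSet | Sequence[str],
    cost: float = DEFAULT_COST,
    floor: int = 1,
    chunk: int = 1,
    variant: KldVariant = "crossentropy",
    level: Literal["sample", "compound"] = "sample",
    tol: float = 1e-3,
) -> EliminationTrace:
    """Eliminate analytes one by one, always removing the least informative.

    At each step every remaining analyte is left out in turn, the LOOCV SVM
    divergence of the reduced panel is computed, and the analyte whose
    removal scores best (smallest divergence for the default variant) is
    eliminated; ties break to the lexicographically smallest gene id.
    Proceeds until ``floor`` analytes remain, then fixes the breakpoint.

    ``chunk`` > 1 removes the k best-scoring analytes per step — an
    approximation for large candidate sets, recorded in the trace metadata
    via each step's own score.
    """
    gene_list = list(candidates.gene_ids) if isinstance(candidates, CandidateSet) else list(candidates)
    if len(gene_list) < 2:
        raise ValueError("need at least 2 candidate analytes")
    if floor < 1:
        raise ValueError("floor must be >= 1")
    if chunk < 1:
        raise ValueError("chunk must be >= 1")
    X, y, _sub = _chemical_xy(ds, gene_list)
    groups = _sub["compound_id"].to_numpy() if level == "compound" else None
    minimize = variant == "crossentropy"

    remaining = list(gene_list)
    col = {g: i for i, g in enumerate(gene_list)}
    initial_d = loocv_decision_values(
        X, y, cost=cost, tol=tol, groups=groups
    )
    initial = _score(initial_d, y, variant)
    steps: list[EliminationStep] = []
    logger.info("backward elimination: %d candidates, initial KLD %.4f", len(remaining), initial)
    while len(remaining) > floor:
        idx = np.array([col[g] for g in remaining])
        scores = np.empty(len(remaining))
        for j in range(len(remaining)):
            keep = np.delete(idx, j)
            d = loocv_decision_values(X[:, keep], y, cost=cost, tol=tol, groups=groups)
            scores[j] = _score(d, y, variant)
        order = sorted(
            range(len(remaining)),
            key=lambda j: ((scores[j] if minimize else -scores[j]), remaining[j]),
        )
        n_out = min(chunk, len(remaining) - floor)
        for j in order[:n_out]:
            steps.append(
                EliminationStep(remaining[j], float(scores[j]), 0)  # n filled below
            )
        eliminated_now = {remaining[j] for j in order[:n_out]}
        remaining = [g for g in remaining if g not in eliminated_now]
    # fill n_remaining: strictly decreasing by one per recorded step
    n0 = len(gene_list)
    steps = [
        EliminationStep(s.eliminated_gene, s.kld_after, n0 - i - 1)
        for i, s in enumerate(steps)
    ]
    trace = EliminationTrace(
        candidates=gene_list, steps=steps, initial_kld=initial, variant=variant
    )
    find_breakpoint(trace)
    logger.info(
        "elimination done: breakpoint at step %d, signature size %d",
        trace.breakpoint_step, len(trace.signature),
    )
    return trace


def find_breakpoint(trace: EliminationTrace) -> tuple[int, list[str]]:
    """Locate the trajectory's global optimum and fix the signature.

    The breakpoint is the step achieving the global minimum recorded
    divergence (maximum for the Gaussian separation variant); ties resolve
    to the latest such step, i.e. the smaller signature.  The signature is
    the candidate set minus everything eliminated through the breakpoint.
    Results are stored on the trace and returned.
    """
    if not trace.steps:
        raise ValueError("empty elimination trace")
    traj = trace.kld_trajectory()
    best = traj.min() if trace.variant == "crossentropy" else traj.max()
    step = int(np.nonzero(traj == best)[0][-1]) + 1  # 1-based, latest tie
    eliminated = {s.eliminated_gene for s in trace.steps[:step]}
    signature = [g for g in trace.candidates if g not in eliminated]
    trace.breakpoint_step = step
    trace.signature = signature
    return step, signature


def write_trace(trace: EliminationTrace, path) -> None:
    df = trace.to_frame()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# variant: {trace.variant}\n")
        fh.write(f"# initial_kld: {trace.initial_kld:.6g}\n")
        fh.write(f"# breakpoint_step: {trace.breakpoint_step}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_signature(signature: Sequence[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\n")
        for g in signature:
            fh.write(g + "\n")
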