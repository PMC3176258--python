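"""Resampling interrogation of the signature-selection procedure.

The dataset's chemical compounds are split 70/30 into training and test
sets, stratified by class and at the *compound* level (all replicates of a
compound travel together).  The whole selection pipeline — ANOVA filtering,
backward elimination, breakpoint — is re-run on the training samples alone,
an SVM is trained on the resulting test signature, and the held-out samples
are scored by ROC/AUC.  Repeating the split yields a distribution of AUCs
and a per-gene call frequency (how often each gene re-enters the signature).

A single-marker baseline screen (per-compound t test against matching
vehicle controls) is included for comparison with one-biomarker assays.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve as _sk_roc_curve, roc_auc_score

from .dataio import (
    CLASS_CONTROL,
    CLASS_NONSENSITIZER,
    CLASS_SENSITIZER,
    Dataset,
    VEHICLE_TOKENS,
)
from .diffexpr import anova_two_group, select_candidates
from .elimination import EliminationTrace, backward_eliminate
from .svm import DEFAULT_COST, loocv_decision_values, train_classifier

logger = logging.getLogger(__name__)


@dataclass
class SplitPlan:
    """One stratified compound-level train/test partition."""

    iteration: int
    seed: int
    train_compounds: list[str]
    test_compounds: list[str]


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


class ConfusionMetrics(NamedTuple):
    sensitivity: float
    specificity: float
    accuracy: float


@dataclass
class IterationResult:
    plan: SplitPlan
    signature: list[str]
    roc: ROCCurve
    metrics: ConfusionMetrics | None = None  # at the training-Youden threshold
    trace: EliminationTrace | None = None


@dataclass
class ValidationResult:
    iterations: list[IterationResult]
    mean_auc: float
    call_frequency: pd.Series  # percent, per gene

    @property
    def aucs(self) -> np.ndarray:
        return np.array([it.roc.auc for it in self.iterations])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(ds: Dataset, train_frac: float = 0.7, seed: int = 0,
                     iteration: int = 0) -> SplitPlan:
    """Partition chemical compounds per class, uniformly at random under seed.

    Per class, round(train_frac * class size) compounds (round half up) go to
    training, with at least one test compound guaranteed.  Vehicle controls
    are not part of the split.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    chem = ds.annot[~ds.annot["compound_id"].isin(VEHICLE_TOKENS)]
    for label in (CLASS_SENSITIZER, CLASS_NONSENSITIZER):
        comps = sorted(set(chem.loc[chem["class_label"] == label, "compound_id"]))
        if len(comps) < 2:
            raise ValueError(f"need >= 2 compounds of class {label!r} to split")
        n_train = _round_half_up(train_frac * len(comps))
        n_train = min(n_train, len(comps) - 1)  # at least one test compound
        n_train = max(n_train, 1)
        perm = rng.permutation(len(comps))
        train.extend(comps[i] for i in perm[:n_train])
        test.extend(comps[i] for i in perm[n_train:])
    return SplitPlan(iteration=iteration, seed=seed, train_compounds=sorted(train),
                     test_compounds=sorted(test))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCCurve:
    """ROC curve and AUC with the sensitizer class positive.

    AUC uses trapezoidal integration over the tie-grouped threshold sweep,
    which equals the Mann-Whitney concordance probability with half credit
    for ties.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present for ROC")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    return ROCCurve(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc)


def confusion_metrics(calls: Sequence[int], truth: Sequence[int]) -> ConfusionMetrics:
    """Sensitivity, specificity and accuracy of binary calls against truth."""
    c = np.asarray(calls).astype(bool)
    t = np.asarray(truth).astype(bool)
    if c.size == 0 or c.shape != t.shape:
        raise ValueError("calls and truth must be non-empty and aligned")
    if t.all() or not t.any():
        raise ValueError("truth must contain both classes")
    tp = int((c & t).sum())
    tn = int((~c & ~t).sum())
    fp = int((c & ~t).sum())
    fn = int((~c & t).sum())
    return ConfusionMetrics(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        accuracy=(tp + tn) / c.size,
    )


def single_marker_screen(
    ds: Dataset, gene: str, alpha: float = 0.05
) -> tuple[pd.DataFrame, ConfusionMetrics]:
    """Single-biomarker baseline: per-compound t test against vehicle controls.

    For each chemical compound, its replicates' expression of ``gene`` is
    compared with the matching-vehicle control replicates by a two-sided
    pooled-variance t test; the compound is called positive when p < alpha
    and the marker is elevated.  Returns the per-compound calls and the
    confusion metrics against the class labels (sensitizer = positive).
    """
    if gene not in ds.expr.index:
        raise KeyError(f"gene {gene!r} not in dataset")
    expr = ds.expr.loc[gene]
    controls = {
        v: expr[ds.annot.index[ds.annot["compound_id"] == tok]]
        for tok, v in zip(VEHICLE_TOKENS, ("DMSO", "water"))
    }
    if all(len(v) == 0 for v in controls.values()):
        raise ValueError("no vehicle-control samples present")
    rows = []
    for comp in ds.compounds():
        sel = ds.annot["compound_id"] == comp
        vals = expr[ds.annot.index[sel]]
        vehicle = ds.annot.loc[sel, "vehicle"].iloc[0]
        ref = controls.get(vehicle)
        if ref is None or len(ref) == 0:
            raise ValueError(f"no {vehicle!r} vehicle controls for compound {comp!r}")
        t, p = sps.ttest_ind(vals, ref, equal_var=True)
        elevated = vals.mean() > ref.mean()
        rows.append(
            {
                "compound_id": comp,
                "class_label": ds.annot.loc[sel, "class_label"].iloc[0],
                "p_value": float(p),
                "elevated": bool(elevated),
                "positive": bool(p < alpha and elevated),
            }
        )
    calls = pd.DataFrame(rows).set_index("compound_id")
    metrics = confusion_metrics(
        calls["positive"].to_numpy(),
        (calls["class_label"] == CLASS_SENSITIZER).to_numpy(),
    )
    return calls, metrics


def permute_compound_labels(ds: Dataset, seed: int = 0) -> Dataset:
    """Null-model dataset: class labels permuted at the compound level.

    The multiset of compound class labels is shuffled and reassigned, with
    all replicates of a compound keeping one label and potency annotations
    rewritten to stay consistent (sensitizers get a placeholder potency).
    Vehicle controls are untouched.
    """
    rng = np.random.default_rng(seed)
    chem = ds.annot[~ds.annot["compound_id"].isin(VEHICLE_TOKENS)]
    comps = list(dict.fromkeys(chem["compound_id"]))
    labels = [chem.loc[chem["compound_id"] == c, "class_label"].iloc[0] for c in comps]
    shuffled = [labels[i] for i in rng.permutation(len(labels))]
    annot = ds.annot.copy()
    for comp, lab in zip(comps, shuffled):
        sel = annot["compound_id"] == comp
        annot.loc[sel, "class_label"] = lab
        annot.loc[sel, "potency"] = "moderate" if lab == CLASS_SENSITIZER else "none"
    return Dataset(ds.expr, annot)


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Decision threshold maximizing Youden's J = sensitivity + specificity - 1.

    Typically applied to training LOOCV decision values to fix the operating
    point before looking at held-out samples.  Ties resolve to the largest
    threshold (the more specific operating point).
    """
    roc = roc_auc(scores, labels)
    j = roc.tpr - roc.fpr
    best = int(np.nonzero(j == j.max())[0][0])
    thr = roc.thresholds[best]
    return float(thr) if np.isfinite(thr) else float(np.max(scores))


def _iteration_seed(master_seed: int, iteration: int) -> int:
    """Per-iteration split seed derived from the master seed."""
    return int(
        np.random.SeedSequence([master_seed, iteration]).generate_state(1)[0] % (2**31)
    )


def run_validation(
    ds: Dataset,
    n_iter: int = 20,
    train_frac: float = 0.7,
    top_k: int | None = None,
    threshold: float | None = None,
    signature_mode: Literal["breakpoint", "fixed"] = "breakpoint",
    signature_size: int | None = None,
    cost: float = DEFAULT_COST,
    floor: int = 1,
    chunk: int = 1,
    seed: int = 0,
) -> ValidationResult:
    """Repeatedly re-derive the signature on training compounds and score the
    held-out compounds' samples by ROC/AUC.

    Candidate filtering (``top_k`` or p ``threshold``) and backward
    elimination see training samples only.  ``signature_mode='breakpoint'``
    takes the trace's breakpoint signature; ``'fixed'`` takes the panel
    remaining when ``signature_size`` analytes are left.  Per-iteration
    split seeds derive deterministically from ``seed``.
    """
    if signature_mode == "fixed" and not signature_size:
        raise ValueError("signature_mode='fixed' requires signature_size")
    iterations: list[IterationResult] = []
    for it in range(n_iter):
        plan = stratified_split(
            ds, train_frac=train_frac, seed=_iteration_seed(seed, it), iteration=it
        )
        train_ds = ds.subset_compounds(plan.train_compounds)
        test_ds = ds.subset_compounds(plan.test_compounds)
        p2 = anova_two_group(train_ds)
        stats_df = pd.DataFrame({"p_two_group": p2})
        cands = select_candidates(stats_df, "two_group", threshold=threshold, top_k=top_k)
        eff_floor = signature_size if signature_mode == "fixed" else floor
        trace = backward_eliminate(
            train_ds, cands, cost=cost, floor=eff_floor, chunk=chunk
        )
        if signature_mode == "fixed":
            signature = [
                g for g in trace.candidates
                if g not in {s.eliminated_gene for s in trace.steps}
            ]
        else:
            signature = trace.signature
        chem_train = train_ds.annot["class_label"] != CLASS_CONTROL
        Xtr = train_ds.expr.loc[signature, chem_train[chem_train].index].to_numpy().T
        ytr = np.where(
            train_ds.annot.loc[chem_train, "class_label"] == CLASS_SENSITIZER, 1, -1
        )
        clf = train_classifier(Xtr, ytr, cost=cost, gene_ids=signature)
        chem_test = test_ds.annot["class_label"] != CLASS_CONTROL
        Xte = test_ds.expr.loc[signature, chem_test[chem_test].index].to_numpy().T
        yte = (
            test_ds.annot.loc[chem_test, "class_label"] == CLASS_SENSITIZER
        ).to_numpy().astype(int)
        scores = clf.decision_values(Xte)
        roc = roc_auc(scores, yte)
        # operating point fixed on training LOOCV scores (Youden's J), then
        # applied to the held-out samples
        d_train = loocv_decision_values(Xtr, ytr, cost=cost)
        thr = youden_threshold(d_train, (ytr > 0).astype(int))
        metrics = confusion_metrics((scores >= thr).astype(int), yte)
        logger.info(
            "validation iteration %d: signature %d genes, test AUC %.3f, "
            "accuracy %.3f", it, len(signature), roc.auc, metrics.accuracy,
        )
        iterations.append(IterationResult(plan=plan, signature=signature, roc=roc,
                                          metrics=metrics, trace=trace))
    all_genes = sorted(set().union(*(it.signature for it in iterations)))
    freq = pd.Series(
        {
            g: 100.0 * sum(g in it.signature for it in iterations) / n_iter
            for g in all_genes
        },
        name="call_frequency",
    )
    mean_auc = float(np.mean([it.roc.auc for it in iterations]))
    return ValidationResult(iterations=iterations, mean_auc=mean_auc, call_frequency=freq)


def write_validation(result: ValidationResult, auc_path, freq_path) -> None:
    pd.DataFrame(
        {
            "iteration": [it.plan.iteration for it in result.iterations],
            "seed": [it.plan.seed for it in result.iterations],
            "signature_size": [len(it.signature) for it in result.iterations],
            "auc": [it.roc.auc for it in result.iterations],
            "sensitivity": [it.metrics.sensitivity if it.metrics else np.nan
                            for it in result.iterations],
            "specificity": [it.metrics.specificity if it.metrics else np.nan
                            for it in result.iterations],
            "accuracy": [it.metrics.accuracy if it.metrics else np.nan
                         for it in result.iterations],
        }
    ).to_csv(auc_path, sep="\t", index=False, float_format="%.6g")
    out = result.call_frequency.rename_axis("gene_id").reset_index()
    out.to_csv(freq_path, sep="\t", index=False, float_format="%.6g")
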