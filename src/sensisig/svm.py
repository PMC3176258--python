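"""Linear soft-margin SVM with sigmoid (Platt) probability calibration.

The classifier is the standard L2-regularized hinge-loss SVM with the
intercept handled as an augmented constant feature, i.e. exactly the
objective solved by liblinear-style dual coordinate descent:

    min_w  0.5 ||w||^2 + C * sum_i max(0, 1 - y_i w.x_i)

Backward elimination evaluates on the order of 10^5-10^6 leave-one-out
fits, so the dual coordinate-descent solver is compiled with numba and the
LOOCV loop exploits the KKT conditions: removing a sample with zero dual
weight (a non-support vector) leaves the optimum unchanged, so only folds
that drop a support vector are refit (warm-started from the full solution).

Decision values are mapped to class probabilities by Platt scaling,
p = 1 / (1 + exp(A*d + B)), fitted by the standard Newton method with
Platt's target smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

#: default regularization cost, matching common SVM library defaults
DEFAULT_COST = 1.0
#: probability clipping bound — keeps log-loss / KLD finite on separable data
PROB_CLIP = 1e-6


@njit(cache=True)
def _dual_cd(Xb, y, C, alpha, tol, max_sweeps):  # pragma: no cover - jitted
    """Dual coordinate descent for the hinge-loss SVM; updates alpha in place.

    ``Xb`` carries the augmented bias column.  Deterministic cyclic sweeps;
    stops when the maximal projected gradient falls below ``tol``.
    Returns the primal weight vector (last entry = bias).
    """
    n, d = Xb.shape
    w = np.zeros(d)
    for i in range(n):
        if alpha[i] != 0.0:
            for j in range(d):
                w[j] += alpha[i] * y[i] * Xb[i, j]
    qd = np.empty(n)
    for i in range(n):
        s = 0.0
        for j in range(d):
            s += Xb[i, j] * Xb[i, j]
        qd[i] = s
    for _ in range(max_sweeps):
        max_pg = 0.0
        for i in range(n):
            g = 0.0
            for j in range(d):
                g += w[j] * Xb[i, j]
            g = y[i] * g - 1.0
            a = alpha[i]
            if a <= 0.0:
                pg = g if g < 0.0 else 0.0
            elif a >= C:
                pg = g if g > 0.0 else 0.0
            else:
                pg = g
            if abs(pg) > max_pg:
                max_pg = abs(pg)
            if pg != 0.0 and qd[i] > 0.0:
                anew = a - g / qd[i]
                if anew < 0.0:
                    anew = 0.0
                elif anew > C:
                    anew = C
                if anew != a:
                    delta = (anew - a) * y[i]
                    for j in range(d):
                        w[j] += delta * Xb[i, j]
                    alpha[i] = anew
        if max_pg < tol:
            break
    return w


@njit(cache=True)
def _loocv_decisions(Xb, y, C, tol, max_sweeps):  # pragma: no cover - jitted
    """Leave-one-out decision values for every sample.

    Non-support-vector folds reuse the full-data solution (exact by KKT);
    support-vector folds are refit warm-started from it.
    """
    n, d = Xb.shape
    alpha = np.zeros(n)
    w = _dual_cd(Xb, y, C, alpha, tol, max_sweeps)
    dvals = np.empty(n)
    Xr = np.empty((n - 1, d))
    yr = np.empty(n - 1)
    ar = np.empty(n - 1)
    for i in range(n):
        if alpha[i] == 0.0:
            s = 0.0
            for j in range(d):
                s += w[j] * Xb[i, j]
            dvals[i] = s
        else:
            k = 0
            for t in range(n):
                if t != i:
                    for j in range(d):
                        Xr[k, j] = Xb[t, j]
                    yr[k] = y[t]
                    ar[k] = alpha[t]
                    k += 1
            wr = _dual_cd(Xr, yr, C, ar, tol, max_sweeps)
            s = 0.0
            for j in range(d):
                s += wr[j] * Xb[i, j]
            dvals[i] = s
    return dvals


def fit_platt(decision_values: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit sigmoid parameters (A, B) with p(+1|d) = 1/(1+exp(A*d+B)).

    Newton iteration on the regularized log-loss with Platt's smoothed
    targets; deterministic.
    """
    d = np.asarray(decision_values, dtype=float)
    y = np.asarray(y)
    pos = y > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("sigmoid calibration needs both classes")
    t = np.where(pos, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    A, B = 0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))
    for _ in range(100):
        z = A * d + B
        p = np.where(z >= 0, np.exp(-z) / (1 + np.exp(-z)), 1 / (1 + np.exp(z)))
        g = p - t  # d(loss)/dz per sample (loss = -t*log p - (1-t)*log(1-p))
        grad_A = np.dot(g, -d)
        grad_B = -g.sum()
        wgt = p * (1 - p) + 1e-12
        h_AA = np.dot(wgt, d * d) + 1e-12
        h_AB = np.dot(wgt, d)
        h_BB = wgt.sum() + 1e-12
        det = h_AA * h_BB - h_AB * h_AB
        dA = (h_BB * grad_A - h_AB * grad_B) / det
        dB = (h_AA * grad_B - h_AB * grad_A) / det
        A -= dA
        B -= dB
        if abs(dA) + abs(dB) < 1e-10:
            break
    return float(A), float(B)


def sigmoid_probability(decision_values: np.ndarray, A: float, B: float) -> np.ndarray:
    """Calibrated probability of the positive class, clipped away from {0,1}."""
    from scipy.special import expit

    z = A * np.asarray(decision_values, dtype=float) + B
    return np.clip(expit(-z), PROB_CLIP, 1 - PROB_CLIP)


@dataclass
class MarginClassifier:
    """A trained linear SVM: weights, offset, per-gene scaling and calibration."""

    gene_ids: list[str]
    weights: np.ndarray
    offset: float
    center: np.ndarray
    scale: np.ndarray
    A: float
    B: float

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Signed margins for rows of X (samples x genes, original scale)."""
        Xs = (np.asarray(X, dtype=float) - self.center) / self.scale
        return Xs @ self.weights + self.offset

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        """Calibrated probability of the positive class."""
        return sigmoid_probability(self.decision_values(X), self.A, self.B)


def zscale_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature center/scale from training data; constant features get scale 1."""
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    return center, scale


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    cost: float = DEFAULT_COST,
    gene_ids: list[str] | None = None,
    tol: float = 1e-8,
    max_sweeps: int = 100_000,
) -> MarginClassifier:
    """Train a linear soft-margin SVM with z-scaling and Platt calibration.

    ``y`` holds +1/-1 labels (or anything with sign); features are z-scaled
    with training statistics.  The calibration sigmoid is fitted on the
    training decision values.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.where(np.asarray(y) > 0, 1.0, -1.0)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be samples x features aligned with y")
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    center, scale = zscale_fit(X)
    Xs = (X - center) / scale
    Xb = np.ascontiguousarray(np.hstack([Xs, np.ones((X.shape[0], 1))]))
    alpha = np.zeros(X.shape[0])
    w = _dual_cd(Xb, y, float(cost), alpha, tol, max_sweeps)
    d = Xb @ w
    A, B = fit_platt(d, y)
    if gene_ids is None:
        gene_ids = [f"f{i}" for i in range(X.shape[1])]
    return MarginClassifier(
        gene_ids=list(gene_ids),
        weights=w[:-1],
        offset=float(w[-1]),
        center=center,
        scale=scale,
        A=A,
        B=B,
    )


def loocv_decision_values(
    X: np.ndarray,
    y: np.ndarray,
    cost: float = DEFAULT_COST,
    tol: float = 1e-3,
    max_sweeps: int = 2000,
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """Cross-validated decision values: each sample (or group) predicted by
    a model trained on all the others.

    Features are z-scaled once per call with the statistics of all samples
    in ``X``.  With ``groups``, whole groups (e.g. all replicates of one
    compound) are left out together.
    """
    X = np.ascontiguousarray(X, dtype=float)
    y = np.where(np.asarray(y) > 0, 1.0, -1.0)
    center, scale = zscale_fit(X)
    Xs = (X - center) / scale
    Xb = np.ascontiguousarray(np.hstack([Xs, np.ones((X.shape[0], 1))]))
    if groups is None:
        for cls in (1.0, -1.0):
            if (y == cls).sum() < 2:
                raise ValueError("need >= 2 samples per class for LOOCV")
        return _loocv_decisions(Xb, y, float(cost), tol, max_sweeps)
    groups = np.asarray(groups)
    dvals = np.empty(X.shape[0])
    for g in np.unique(groups):
        test = groups == g
        ytr = y[~test]
        if np.unique(ytr).size < 2:
            raise ValueError(f"leaving out group {g!r} empties a class")
        alpha = np.zeros(int((~test).sum()))
        w = _dual_cd(
            np.ascontiguousarray(Xb[~test]), ytr, float(cost), alpha, tol, max_sweeps
        )
        dvals[test] = Xb[test] @ w
    return dvals
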