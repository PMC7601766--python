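"""Binary PLS-DA: NIPALS fitting, classification, LOO-CV latent-variable
selection and ROC/AUC evaluation.

The class membership is coded {0, 1} and regressed on the spectra by PLS1;
a sample is assigned to the positive class when its predicted response
reaches the decision threshold (default 0.5, ties to the positive class).
ROC curves sweep that threshold over all distinct predicted scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiscriminantModel",
    "ROCCurve",
    "fit_pls",
    "predict_response",
    "classify",
    "loo_cv_select_A",
    "roc_curve",
]

_TOL = 1e-10
_MAX_ITER = 500


@dataclass(frozen=True)
class DiscriminantModel:
    x_weights: np.ndarray   # (p, A)
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    coef: np.ndarray        # (p,) regression vector on the original channel scale
    coef_path: np.ndarray   # (p, A): regression vector using the first a components
    intercept: float
    x_mean: np.ndarray
    y_mean: float
    n_components: int
    classes: tuple = (0, 1)  # labels coded 0 and 1, in that order
    threshold: float = 0.5


@dataclass(frozen=True)
class ROCCurve:
    fpr: np.ndarray         # 1 - specificity, non-decreasing from 0 to 1
    tpr: np.ndarray         # sensitivity, non-decreasing from 0 to 1
    thresholds: np.ndarray  # descending; sentinels beyond min/max scores
    auc: float


def _nipals(xc: np.ndarray, yc: np.ndarray, n_components: int,
            tol: float = _TOL, max_iter: int = _MAX_ITER) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Deterministic NIPALS with deflation on centered data.

    For a univariate response the weight update w = X'y is exact after one
    pass; the iteration loop only guards the general case.  Returns weights,
    x-loadings, y-loadings and the number of components actually extracted
    (fewer than requested when the residual rank is exhausted).
    """
    n, p = xc.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    c = np.zeros(n_components)
    x, y = xc.copy(), yc.copy()
    extracted = 0
    for a in range(n_components):
        u = y  # deterministic start: the (deflated) response itself
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = x.T @ u
            norm = np.linalg.norm(w_new)
            if norm < _TOL:
                return W[:, :extracted], P[:, :extracted], c[:extracted], extracted
            w_new = w_new / norm
            t = x @ w_new
            tt = float(t @ t)
            if tt < _TOL:
                return W[:, :extracted], P[:, :extracted], c[:extracted], extracted
            c_a = float(y @ t) / tt
            u = y * c_a
            converged = np.linalg.norm(w_new - w) < tol
            w = w_new
            if converged:
                break
        t = x @ w
        tt = float(t @ t)
        if tt < _TOL:
            break
        p_a = x.T @ t / tt
        c_a = float(y @ t) / tt
        x = x - np.outer(t, p_a)
        y = y - c_a * t
        W[:, a], P[:, a], c[a] = w, p_a, c_a
        extracted += 1
    return W[:, :extracted], P[:, :extracted], c[:extracted], extracted


def _coef_path(W: np.ndarray, P: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Regression vectors B_a = W_a (P_a' W_a)^-1 c_a for every a = 1..A."""
    p, A = W.shape
    path = np.zeros((p, A))
    for a in range(1, A + 1):
        r = np.linalg.solve(P[:, :a].T @ W[:, :a], c[:a])
        path[:, a - 1] = W[:, :a] @ r
    return path


def fit_pls(X: np.ndarray, y_coded: np.ndarray, n_components: int,
            classes: tuple = (0, 1), threshold: float = 0.5) -> DiscriminantModel:
    """Fit a PLS1 discriminant on {0,1}-coded class membership.

    Centering of X and y is performed (and stored) here, so the same routine
    serves both pipeline-centered training data and raw leave-one-out folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_coded, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y length mismatch")
    if np.unique(y).size < 2:
        raise ValueError("y contains a single class")
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"number of components {n_components} out of range for {n}x{p} data")
    x_mean, y_mean = X.mean(axis=0), float(y.mean())
    W, P, c, extracted = _nipals(X - x_mean, y - y_mean, n_components)
    if extracted < n_components:
        raise ValueError(f"requested {n_components} components but rank supports only {extracted}")
    path = _coef_path(W, P, c)
    coef = path[:, -1]
    return DiscriminantModel(
        x_weights=W, x_loadings=P, y_loadings=c, coef=coef, coef_path=path,
        intercept=y_mean - float(x_mean @ coef), x_mean=x_mean, y_mean=y_mean,
        n_components=extracted, classes=tuple(classes), threshold=threshold,
    )


def predict_response(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.coef.size:
        raise ValueError("channel count does not match model")
    return X @ model.coef + model.intercept


def classify(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    """Assign the positive class when the predicted response reaches the threshold."""
    yhat = predict_response(model, X)
    labels = np.where(yhat >= model.threshold, model.classes[1], model.classes[0])
    return labels


def _rowspace(X: np.ndarray) -> np.ndarray:
    """Exact coordinates of the rows in an orthonormal basis of the centered row span.

    PLS is equivariant under rotation of the channel axis, and every fold mean,
    weight and regression vector of a leave-one-out fold lies in the span of the
    centered training rows, so running LOO on these coordinates reproduces the
    full-dimensional result exactly while shrinking p to at most n.
    """
    mu = X.mean(axis=0)
    u, s, _ = np.linalg.svd(X - mu, full_matrices=False)
    keep = s > max(s[0], 1.0) * 1e-12 if s.size else np.zeros(0, dtype=bool)
    return u[:, keep] * s[keep]


def loo_cv_select_A(X: np.ndarray, y_coded: np.ndarray, a_max: int,
                    threshold: float = 0.5) -> int:
    """Leave-one-out selection of the latent-variable count.

    Returns the smallest A minimising the LOO misclassification count (ties go
    to the most parsimonious model).  Each fold refits centering on its own
    training rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_coded, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOO selection needs at least three samples")
    if np.unique(y).size < 2:
        raise ValueError("y contains a single class")
    a_max = int(min(a_max, n - 2, X.shape[1]))
    if a_max < 1:
        raise ValueError("a_max must allow at least one component")
    Z = _rowspace(X) if X.shape[1] > n else X
    errors = np.zeros(a_max, dtype=int)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        z_tr, y_tr = Z[mask], y[mask]
        if np.unique(y_tr).size < 2:
            continue
        x_mean, y_mean = z_tr.mean(axis=0), float(y_tr.mean())
        a_fold = min(a_max, z_tr.shape[0] - 1, z_tr.shape[1])
        W, P, c, extracted = _nipals(z_tr - x_mean, y_tr - y_mean, a_fold)
        if extracted == 0:
            errors += 1
            continue
        path = _coef_path(W, P, c)
        yhat = (Z[i] - x_mean) @ path + y_mean  # one prediction per component count
        if extracted < a_max:  # rank exhausted: larger A behaves like the largest fitted
            yhat = np.concatenate([yhat, np.full(a_max - extracted, yhat[-1])])
        pred = (yhat >= threshold).astype(float)
        errors += pred != y[i]
    return int(np.argmin(errors)) + 1  # argmin takes the first (smallest A) on ties


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC over all decision thresholds, with trapezoid AUC.

    Thresholds sit at midpoints between consecutive distinct scores, plus
    sentinels beyond the extremes, so the curve runs exactly from (0,0) to
    (1,1).  The trapezoid AUC equals the rank statistic
    P(score_pos > score_neg) + 0.5 P(equal).
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    if scores.size != labels.size:
        raise ValueError("scores and labels length mismatch")
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    thresholds = np.concatenate([[u[-1] + 1.0], mids[::-1], [u[0] - 1.0]])
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for j, thr in enumerate(thresholds):
        pred = scores >= thr
        tpr[j] = np.count_nonzero(pred & labels) / n_pos
        fpr[j] = np.count_nonzero(pred & ~labels) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)
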