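"""One-class SIMCA: a PCA model of the target class with a combined
Hotelling-T2 / Q-residual acceptance rule.

A tested sample's score distance T2 (Mahalanobis, within the k-component
inner space) and orthogonal distance Q (squared residual norm outside it) are
divided by their critical limits; the sample is accepted when the Euclidean
norm of the reduced pair does not exceed sqrt(2) — i.e. the limit any sample
reaches when both statistics sit exactly at their individual critical values.

Critical limits follow the conventional constructions:
  T2_lim = k (n-1) / (n-k) * F_{1-alpha}(k, n-k)
  Q_lim  = g * chi2_{1-alpha}(h)   with g = v / (2 m), h = 2 m^2 / v,
where m and v are the mean and variance of the training Q values (the Box
moment approximation, which does not require the residual eigenvalue
spectrum when channels >> samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .latent import PCAModel, choose_k_by_variance, fit_pca, project

__all__ = [
    "ClassModel",
    "Decisions",
    "SimcaMetrics",
    "fit_simca",
    "score_samples",
    "sensitivity_specificity",
]

_ACCEPT_RADIUS = np.sqrt(2.0)


@dataclass(frozen=True)
class ClassModel:
    target: str
    pca: PCAModel
    alpha: float
    k: int
    n_train: int
    t2_lim: float
    q_lim: float


@dataclass(frozen=True)
class Decisions:
    """Per-sample SIMCA statistics and the accept/reject outcome."""

    t2: np.ndarray
    q: np.ndarray
    t_reduced: np.ndarray  # T2 / T2_lim
    q_reduced: np.ndarray  # Q / Q_lim
    distance: np.ndarray   # sqrt(t_reduced^2 + q_reduced^2)
    accepted: np.ndarray   # distance <= sqrt(2)


@dataclass(frozen=True)
class SimcaMetrics:
    sensitivity: float  # % of target samples accepted, 1 decimal
    specificity: float  # % of alien samples rejected, 1 decimal
    ccr: float          # % correct overall, 1 decimal
    n_target: int
    n_alien: int


def fit_simca(X_target: np.ndarray, k: int | None = None, alpha: float = 0.05,
              target: str = "target", variance_threshold: float = 0.95) -> ClassModel:
    """Fit the target-class PCA submodel and its T2/Q critical limits.

    ``k=None`` applies the cumulative explained-variance rule (default 95%).
    """
    X = np.asarray(X_target, dtype=float)
    n = X.shape[0]
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if k is None:
        k = min(choose_k_by_variance(X, variance_threshold), n - 2 if n > 2 else 1)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the training size n={n}")
    model = fit_pca(X, k)
    t2_lim = k * (n - 1) / (n - k) * float(stats.f.ppf(1 - alpha, k, n - k))
    scores = project(model, X)
    residual = (X - model.center) - scores @ model.loadings.T
    q_train = np.sum(residual**2, axis=1)
    m = float(q_train.mean())
    v = float(q_train.var(ddof=1))
    if m < 1e-12 or v < 1e-24:
        raise ValueError("zero residual variance: the inner space already spans the data; reduce k")
    g, h = v / (2.0 * m), 2.0 * m**2 / v
    q_lim = g * float(stats.chi2.ppf(1 - alpha, h))
    return ClassModel(target=target, pca=model, alpha=alpha, k=k, n_train=n,
                      t2_lim=t2_lim, q_lim=q_lim)


def score_samples(model: ClassModel, X_new: np.ndarray) -> Decisions:
    """T2, Q and the combined reduced distance for each tested sample."""
    X = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X.shape[1] != model.pca.n_channels:
        raise ValueError("channel count does not match the class model")
    scores = project(model.pca, X)
    lam = model.pca.explained_variance
    t2 = np.sum(scores**2 / lam, axis=1)
    residual = (X - model.pca.center) - scores @ model.pca.loadings.T
    q = np.sum(residual**2, axis=1)
    t_red = t2 / model.t2_lim
    q_red = q / model.q_lim
    distance = np.sqrt(t_red**2 + q_red**2)
    return Decisions(t2=t2, q=q, t_reduced=t_red, q_reduced=q_red,
                     distance=distance, accepted=distance <= _ACCEPT_RADIUS)


def sensitivity_specificity(accepted: np.ndarray, true_labels: np.ndarray,
                            target: str) -> SimcaMetrics:
    """Sensitivity, specificity and overall CCR of one-class decisions, in %.

    Sensitivity is the fraction of target (compliant) samples accepted,
    specificity the fraction of alien samples rejected; both are reported to
    one decimal place.
    """
    accepted = np.asarray(accepted, dtype=bool).ravel()
    labels = np.asarray(true_labels).ravel()
    if accepted.size != labels.size:
        raise ValueError("decision and label vectors differ in length")
    is_target = labels == target
    n_target = int(is_target.sum())
    n_alien = int((~is_target).sum())
    if n_target == 0:
        raise ValueError(f"no samples of target class {target!r}")
    if n_alien == 0:
        raise ValueError("no alien samples")
    tp = int(np.count_nonzero(accepted & is_target))
    tn = int(np.count_nonzero(~accepted & ~is_target))
    return SimcaMetrics(
        sensitivity=round(100.0 * tp / n_target, 1),
        specificity=round(100.0 * tn / n_alien, 1),
        ccr=round(100.0 * (tp + tn) / (n_target + n_alien), 1),
        n_target=n_target,
        n_alien=n_alien,
    )
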