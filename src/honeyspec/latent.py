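"""PCA decomposition, projection, component-count selection and QC drift checks.

The decomposition is computed by singular value decomposition of the centered
matrix (stable for channels >> samples).  Component signs follow a fixed
convention — the largest-magnitude loading element of each component is made
positive — so scores and loadings are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import snv as _snv
from .spectra_io import SpectralBlock

__all__ = [
    "PCAModel",
    "DriftReport",
    "fit_pca",
    "project",
    "choose_k_by_variance",
    "qc_drift_check",
]

_RANK_TOL = 1e-10


@dataclass(frozen=True)
class PCAModel:
    center: np.ndarray
    loadings: np.ndarray  # (channels, k), orthonormal columns
    explained_variance: np.ndarray  # per-component score variances (n-1 denominator)
    explained_variance_ratio: np.ndarray  # fractions of total centered variance
    k: int

    @property
    def n_channels(self) -> int:
        return self.center.size


def fit_pca(matrix: np.ndarray, k: int) -> PCAModel:
    """PCA of ``matrix`` (rows = samples); centering is performed and stored here."""
    x = np.asarray(matrix, dtype=float)
    n, p = x.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} out of range for a {n}x{p} matrix")
    center = x.mean(axis=0)
    xc = x - center
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float((s**2).sum())
    loadings = vt[:k].T.copy()
    # sign convention: largest-magnitude loading element positive per component
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings *= flip
    var = s[:k] ** 2 / max(n - 1, 1)
    ratio = s[:k] ** 2 / total if total > 0 else np.zeros(k)
    return PCAModel(center=center, loadings=loadings, explained_variance=var,
                    explained_variance_ratio=ratio, k=k)


def project(model: PCAModel, matrix: np.ndarray) -> np.ndarray:
    """Scores of new rows: (data - center) @ loadings."""
    x = np.atleast_2d(np.asarray(matrix, dtype=float))
    if x.shape[1] != model.n_channels:
        raise ValueError(f"channel count {x.shape[1]} does not match model ({model.n_channels})")
    return (x - model.center) @ model.loadings


def choose_k_by_variance(source: "PCAModel | np.ndarray", threshold: float = 0.95) -> int:
    """Smallest k whose cumulative explained-variance fraction reaches ``threshold``.

    ``source`` may be a fitted model, a vector of explained-variance fractions,
    or a data matrix (in which case a full-rank PCA is fitted first).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if isinstance(source, PCAModel):
        fractions = source.explained_variance_ratio
    else:
        arr = np.asarray(source, dtype=float)
        if arr.ndim == 1:
            fractions = arr
        else:
            n, p = arr.shape
            fractions = fit_pca(arr, min(n - 1, p)).explained_variance_ratio
    nonzero = fractions > _RANK_TOL
    cum = np.cumsum(fractions)
    reached = np.nonzero(cum >= threshold - 1e-12)[0]
    if reached.size == 0:
        return int(nonzero.sum())
    return int(min(reached[0] + 1, max(int(nonzero.sum()), 1)))


@dataclass(frozen=True)
class DriftReport:
    """Per-batch QC drift summary from a pooled PCA of quality-control scans."""

    k: int
    limit: float
    distances: dict[str, float]  # squared Mahalanobis distance of each batch centroid
    flagged: tuple[str, ...]

    @property
    def any_flagged(self) -> bool:
        return len(self.flagged) > 0


def qc_drift_check(batches: "dict[str, SpectralBlock] | list[SpectralBlock]",
                   quantile: float = 0.99, apply_snv: bool = True,
                   variance_threshold: float = 0.95, max_k: int = 10) -> DriftReport:
    """Flag QC batches whose score centroid drifts from the pooled centroid.

    QC spectra are SNV-pretreated (removing per-scan offset/gain), pooled, and
    decomposed by PCA.  Each batch centroid's squared Mahalanobis distance in
    score space, scaled by the batch size (a mean-shift statistic), is compared
    with the chi-squared ``quantile`` at k degrees of freedom.
    """
    if isinstance(batches, dict):
        names = list(batches)
        blocks = [batches[n] for n in names]
    else:
        names = [f"batch{i + 1}" for i in range(len(batches))]
        blocks = list(batches)
    if len(blocks) < 2:
        raise ValueError("drift check needs at least two QC batches")
    if apply_snv:
        blocks = [_snv(b) for b in blocks]
    pooled = np.vstack([b.intensities for b in blocks])
    sizes = [b.intensities.shape[0] for b in blocks]
    centered = pooled - pooled.mean(axis=0)
    total_var = float((centered**2).sum())
    if total_var < _RANK_TOL:  # identical QC spectra everywhere: no drift by definition
        return DriftReport(k=0, limit=float("inf"),
                           distances={n: 0.0 for n in names}, flagged=())
    k_full = min(pooled.shape[0] - 1, pooled.shape[1])
    model = fit_pca(pooled, k_full)
    k = min(choose_k_by_variance(model, variance_threshold), max_k)
    model = fit_pca(pooled, k)
    scores = project(model, pooled)
    lam = np.maximum(model.explained_variance, _RANK_TOL)
    limit = float(stats.chi2.ppf(quantile, df=k))
    distances: dict[str, float] = {}
    flagged = []
    start = 0
    for name, size in zip(names, sizes):
        centroid = scores[start:start + size].mean(axis=0)
        d2 = float(size * np.sum(centroid**2 / lam))
        distances[name] = d2
        if d2 > limit:
            flagged.append(name)
        start += size
    return DriftReport(k=k, limit=limit, distances=distances, flagged=tuple(flagged))
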