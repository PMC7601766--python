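"""Multi-block data fusion of the three spectroscopic platforms.

Low level:  column-wise concatenation of the per-platform preprocessed
            matrices, autoscaled with training-row statistics.
Mid level:  per-block PCA on the training rows; test rows projected; the
            concatenated score blocks are autoscaled (score magnitudes differ
            across platforms by orders of magnitude).
High level: majority vote over the per-platform classifier decisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .latent import PCAModel, choose_k_by_variance, fit_pca, project
from .spectra_io import SpectralBlock

__all__ = ["FusedMatrix", "low_level_fuse", "mid_level_fuse", "high_level_vote"]

_TOL = 1e-12


@dataclass(frozen=True)
class FusedMatrix:
    data: np.ndarray
    sample_keys: tuple[str, ...]
    boundaries: tuple[tuple[str, int, int], ...]  # (platform tag, start, stop) per column range
    level: str
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    block_models: tuple[PCAModel, ...] = ()  # mid-level only

    @property
    def width(self) -> int:
        return self.data.shape[1]

    def block(self, tag: str) -> np.ndarray:
        for name, start, stop in self.boundaries:
            if name == tag:
                return self.data[:, start:stop]
        raise KeyError(tag)


def _check_aligned(blocks: Sequence[SpectralBlock]) -> tuple[str, ...]:
    keys = tuple(blocks[0].sample_keys)
    for block in blocks[1:]:
        if tuple(block.sample_keys) != keys:
            raise ValueError("blocks are not aligned: sample keys or order differ")
    return keys


def _autoscale(data: np.ndarray, train_mask: np.ndarray,
               drop_constant: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    train = data[train_mask]
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1) if train.shape[0] > 1 else np.zeros(data.shape[1])
    constant = sd < _TOL
    if constant.any():
        if not drop_constant:
            raise ValueError(f"{int(constant.sum())} zero-variance column(s) in the fused matrix")
        keep = ~constant
    else:
        keep = np.ones(data.shape[1], dtype=bool)
    scaled = (data[:, keep] - mean[keep]) / sd[keep]
    return scaled, mean[keep], sd[keep], keep


def _trim_boundaries(widths: list[tuple[str, int]], keep: np.ndarray) -> tuple[tuple[str, int, int], ...]:
    bounds = []
    start_raw = 0
    start_kept = 0
    for tag, width in widths:
        kept = int(keep[start_raw:start_raw + width].sum())
        bounds.append((tag, start_kept, start_kept + kept))
        start_raw += width
        start_kept += kept
    return tuple(bounds)


def low_level_fuse(blocks: Sequence[SpectralBlock], train_mask: np.ndarray | None = None,
                   drop_constant: bool = True) -> FusedMatrix:
    """Concatenate preprocessed blocks column-wise and autoscale on training rows.

    Each block must already be preprocessed by its own optimal pipeline and
    aligned to the same samples in the same order.
    """
    keys = _check_aligned(blocks)
    n = len(keys)
    mask = np.ones(n, dtype=bool) if train_mask is None else np.asarray(train_mask, dtype=bool)
    if mask.size != n:
        raise ValueError("train_mask length does not match sample count")
    data = np.hstack([b.intensities for b in blocks])
    widths = [(b.platform.value, b.n_channels) for b in blocks]
    scaled, mean, sd, keep = _autoscale(data, mask, drop_constant)
    return FusedMatrix(data=scaled, sample_keys=keys,
                       boundaries=_trim_boundaries(widths, keep), level="low",
                       scale_mean=mean, scale_sd=sd)


def mid_level_fuse(blocks: Sequence[SpectralBlock], train_mask: np.ndarray | None = None,
                   k_rule: "float | Sequence[int]" = 0.95,
                   score_scaling: str = "block") -> FusedMatrix:
    """Fuse per-block PCA scores: PCA fitted on training rows, test rows projected.

    ``k_rule`` is either a cumulative explained-variance threshold applied per
    block, or an explicit component count per block.  ``score_scaling``
    commensurates the blocks, whose score magnitudes differ across platforms
    by orders of magnitude: ``"block"`` (default) centers the scores and
    divides each block by its total training score standard deviation,
    preserving the within-block variance ratios; ``"auto"`` autoscales every
    score column individually (which promotes each block's minor components
    to parity with its leading ones).
    """
    keys = _check_aligned(blocks)
    n = len(keys)
    mask = np.ones(n, dtype=bool) if train_mask is None else np.asarray(train_mask, dtype=bool)
    if mask.size != n:
        raise ValueError("train_mask length does not match sample count")
    n_train = int(mask.sum())
    score_blocks = []
    widths = []
    models = []
    for j, block in enumerate(blocks):
        train = block.intensities[mask]
        if isinstance(k_rule, (int, float)) and not isinstance(k_rule, bool) and float(k_rule) <= 1:
            k = choose_k_by_variance(train, float(k_rule))
        else:
            k = int(k_rule[j]) if not np.isscalar(k_rule) else int(k_rule)
        k = min(k, n_train - 1, block.n_channels)
        if k < 1:
            raise ValueError(f"block {block.platform.value}: no usable components")
        model = fit_pca(train, k)
        score_blocks.append(project(model, block.intensities))
        widths.append((block.platform.value, k))
        models.append(model)
    data = np.hstack(score_blocks)
    if score_scaling == "auto":
        scaled, mean, sd, keep = _autoscale(data, mask, drop_constant=True)
        bounds = _trim_boundaries(widths, keep)
    elif score_scaling == "block":
        mean = data[mask].mean(axis=0)
        sd_parts = []
        for (_, width), model in zip(widths, models):
            total_sd = np.sqrt(np.sum(model.explained_variance))
            sd_parts.append(np.full(width, max(total_sd, _TOL)))
        sd = np.concatenate(sd_parts)
        scaled = (data - mean) / sd
        bounds = _trim_boundaries(widths, np.ones(data.shape[1], dtype=bool))
    else:
        raise ValueError(f"unknown score_scaling {score_scaling!r}")
    return FusedMatrix(data=scaled, sample_keys=keys, boundaries=bounds, level="mid",
                       scale_mean=mean, scale_sd=sd, block_models=tuple(models))


def high_level_vote(predictions: Sequence[Sequence]) -> np.ndarray:
    """Majority vote across per-platform label vectors (one vector per voter).

    An odd voter count is required so that, for binary labels, a strict
    majority always exists.
    """
    votes = np.asarray([np.asarray(p) for p in predictions])
    if votes.ndim != 2:
        raise ValueError("predictions must be equal-length label vectors")
    n_voters = votes.shape[0]
    if n_voters % 2 == 0:
        raise ValueError("tie possible: voter count must be odd")
    out = []
    for column in votes.T:
        labels, counts = np.unique(column, return_counts=True)
        top = int(np.argmax(counts))
        if counts[top] * 2 <= n_voters:
            raise ValueError(f"no strict majority among votes {list(column)}")
        out.append(labels[top])
    return np.asarray(out)
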