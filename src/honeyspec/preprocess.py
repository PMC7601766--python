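"""Spectral pretreatments: SNV, MSC, Savitzky-Golay derivatives, polynomial
baseline subtraction, centering/autoscaling, and their composition into
per-platform pipelines.

Stateful steps (the MSC reference spectrum, column centering statistics) are
fitted on training spectra only and re-applied unchanged to test spectra, so
no test-set statistic ever leaks into a fitted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import RegionSet, SpectralBlock

__all__ = [
    "SNV",
    "MSC",
    "SavGol",
    "Baseline",
    "MeanCenter",
    "Autoscale",
    "PipelineStep",
    "CenteringModel",
    "FittedPipeline",
    "PipelineError",
    "NonUniformAxisWarning",
    "snv",
    "msc",
    "sg_derivative",
    "baseline_poly",
    "fit_centering",
    "apply_centering",
    "fit_pipeline",
    "apply_pipeline",
]

_B_TOL = 1e-12  # minimum |gain| for a valid scatter fit


class PipelineError(RuntimeError):
    """A step of a preprocessing pipeline failed; message carries the step index."""


class NonUniformAxisWarning(UserWarning):
    """Savitzky-Golay filtering applied on a non-uniformly spaced axis."""


# ---------------------------------------------------------------------------
# Step declarations


@dataclass(frozen=True)
class SNV:
    """Standard normal variate: per-spectrum standardisation."""


@dataclass(frozen=True)
class MSC:
    """Multiplicative scatter correction against a reference spectrum.

    ``reference=None`` means the mean spectrum of the fitted (training) set.
    """

    reference: tuple[float, ...] | None = None


@dataclass(frozen=True)
class SavGol:
    deriv: int = 1
    poly: int = 2
    window: int = 9


@dataclass(frozen=True)
class Baseline:
    anchors: RegionSet
    order: int = 3


@dataclass(frozen=True)
class MeanCenter:
    pass


@dataclass(frozen=True)
class Autoscale:
    drop_constant: bool = False


PipelineStep = Union[SNV, MSC, SavGol, Baseline, MeanCenter, Autoscale]


# ---------------------------------------------------------------------------
# Individual transforms


def snv(block: SpectralBlock) -> SpectralBlock:
    """Transform each spectrum to zero mean and unit standard deviation (n-1)."""
    x = block.intensities
    if x.shape[1] < 2:
        raise ValueError("SNV needs at least two channels")
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = np.nonzero(sd.ravel() < _B_TOL)[0]
    if flat.size:
        raise ValueError(f"constant spectrum, SNV undefined for sample {block.sample_keys[flat[0]]!r}")
    return block.with_intensities((x - mean) / sd)


def msc(block: SpectralBlock, reference: np.ndarray | None = None) -> SpectralBlock:
    """Per spectrum, least-squares fit x ~ a + b*reference and return (x - a)/b."""
    x = block.intensities
    ref = x.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.size != x.shape[1]:
        raise ValueError("reference length does not match channel count")
    rc = ref - ref.mean()
    denom = rc @ rc
    if denom < _B_TOL:
        raise ValueError("degenerate scatter fit: constant reference spectrum")
    b = (x - x.mean(axis=1, keepdims=True)) @ rc / denom
    bad = np.nonzero(np.abs(b) < _B_TOL)[0]
    if bad.size:
        raise ValueError(f"degenerate scatter fit for sample {block.sample_keys[bad[0]]!r}")
    a = x.mean(axis=1) - b * ref.mean()
    return block.with_intensities((x - a[:, None]) / b[:, None])


def sg_derivative(block: SpectralBlock, deriv: int, poly: int, window: int) -> SpectralBlock:
    """Savitzky-Golay smoothed derivative, scaled by the (median) channel spacing.

    Edge channels are handled by a one-sided polynomial refit on the truncated
    window rather than by padding with mirrored data.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= poly:
        raise ValueError("window must exceed the polynomial order")
    if window > block.n_channels:
        raise ValueError("window exceeds channel count")
    spacing = np.diff(block.axis)
    delta = float(np.median(spacing))
    # region selection leaves gaps in the axis: filter each contiguous segment
    # separately so the derivative never mixes channels across a gap
    breaks = np.nonzero(spacing > 1.5 * delta)[0] + 1
    segments = np.split(np.arange(block.n_channels), breaks)
    out = np.empty_like(block.intensities)
    for seg in segments:
        if seg.size < window:
            raise ValueError(f"window {window} exceeds a contiguous segment of {seg.size} channels")
        seg_spacing = np.diff(block.axis[seg])
        if np.max(np.abs(seg_spacing - delta)) > 1e-6 * delta:
            warnings.warn(
                "non-uniform channel spacing; Savitzky-Golay assumes the median spacing",
                NonUniformAxisWarning,
                stacklevel=2,
            )
        out[:, seg] = savgol_filter(
            block.intensities[:, seg], window_length=window, polyorder=poly,
            deriv=deriv, delta=delta, axis=1, mode="interp",
        )
    return block.with_intensities(out)


def baseline_poly(block: SpectralBlock, anchors: RegionSet, order: int = 3) -> SpectralBlock:
    """Subtract a polynomial fitted by least squares to the anchor-region channels.

    The anchor regions stand in for manually picked baseline points; the fitted
    curve is evaluated and subtracted over the whole axis.
    """
    if order < 1:
        raise ValueError("baseline polynomial order must be >= 1")
    mask = anchors.mask(block.axis)
    n_anchor = int(mask.sum())
    if n_anchor < order + 1:
        raise ValueError(f"{n_anchor} anchor channels cannot determine an order-{order} polynomial")
    # scale axis to [-1, 1] for Vandermonde conditioning
    lo, hi = block.axis[0], block.axis[-1]
    u = (2.0 * block.axis - (lo + hi)) / (hi - lo)
    van_fit = np.polynomial.polynomial.polyvander(u[mask], order)
    coef, *_ = np.linalg.lstsq(van_fit, block.intensities[:, mask].T, rcond=None)
    fitted = (np.polynomial.polynomial.polyvander(u, order) @ coef).T
    return block.with_intensities(block.intensities - fitted)


# ---------------------------------------------------------------------------
# Centering / autoscaling (training statistics kept separate from data)


@dataclass(frozen=True)
class CenteringModel:
    mean: np.ndarray
    scale: np.ndarray | None = None
    kept: np.ndarray | None = None  # boolean column mask when constants were dropped

    @property
    def autoscaled(self) -> bool:
        return self.scale is not None


def fit_centering(block: SpectralBlock, autoscale: bool = False,
                  drop_constant: bool = False) -> CenteringModel:
    x = block.intensities
    mean = x.mean(axis=0)
    if not autoscale:
        return CenteringModel(mean=mean)
    sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    constant = sd < _B_TOL
    if constant.any() and not drop_constant:
        raise ValueError(
            f"autoscaling undefined for {int(constant.sum())} zero-variance column(s); "
            "use drop_constant to remove them"
        )
    if constant.any():
        keep = ~constant
        return CenteringModel(mean=mean[keep], scale=sd[keep], kept=keep)
    return CenteringModel(mean=mean, scale=sd)


def apply_centering(block: SpectralBlock, model: CenteringModel) -> SpectralBlock:
    x, axis = block.intensities, block.axis
    if model.kept is not None:
        if model.kept.size != x.shape[1]:
            raise ValueError("channel count does not match centering model")
        x, axis = x[:, model.kept], axis[model.kept]
    if x.shape[1] != model.mean.size:
        raise ValueError("channel count does not match centering model")
    out = x - model.mean
    if model.scale is not None:
        out = out / model.scale
    return block.with_intensities(out, axis=axis)


# ---------------------------------------------------------------------------
# Pipelines


@dataclass
class FittedPipeline:
    """Frozen pipeline: steps plus the state fitted on the training spectra."""

    steps: tuple[PipelineStep, ...]
    states: tuple[object, ...]

    def apply(self, block: SpectralBlock) -> SpectralBlock:
        for i, (step, state) in enumerate(zip(self.steps, self.states)):
            try:
                block = _apply_step(block, step, state)
            except Exception as err:
                raise PipelineError(f"step {i} ({type(step).__name__}): {err}") from err
        return block


def _apply_step(block: SpectralBlock, step: PipelineStep, state: object) -> SpectralBlock:
    if isinstance(step, SNV):
        return snv(block)
    if isinstance(step, MSC):
        return msc(block, reference=state)
    if isinstance(step, SavGol):
        return sg_derivative(block, step.deriv, step.poly, step.window)
    if isinstance(step, Baseline):
        return baseline_poly(block, step.anchors, step.order)
    if isinstance(step, (MeanCenter, Autoscale)):
        return apply_centering(block, state)
    raise TypeError(f"unknown pipeline step {step!r}")


def fit_pipeline(block: SpectralBlock, steps: Sequence[PipelineStep]) -> tuple[SpectralBlock, FittedPipeline]:
    """Fit stateful steps on ``block`` (the training set) and transform it."""
    states: list[object] = []
    for i, step in enumerate(steps):
        try:
            if isinstance(step, MSC):
                state = (np.asarray(step.reference, dtype=float)
                         if step.reference is not None else block.intensities.mean(axis=0))
            elif isinstance(step, MeanCenter):
                state = fit_centering(block, autoscale=False)
            elif isinstance(step, Autoscale):
                state = fit_centering(block, autoscale=True, drop_constant=step.drop_constant)
            else:
                state = None
            block = _apply_step(block, step, state)
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"step {i} ({type(step).__name__}): {err}") from err
        states.append(state)
    return block, FittedPipeline(steps=tuple(steps), states=tuple(states))


def apply_pipeline(block: SpectralBlock, steps: Sequence[PipelineStep],
                   fitted: FittedPipeline | None = None) -> SpectralBlock:
    """Apply a pipeline; with ``fitted=None`` the state is fitted on ``block`` itself."""
    if fitted is None:
        out, _ = fit_pipeline(block, steps)
        return out
    if tuple(steps) != fitted.steps:
        raise ValueError("steps do not match the fitted pipeline")
    return fitted.apply(block)
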