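"""Synthetic multi-platform, multi-harvest honey spectra.

The generator emulates the statistical structure the analysis assumes, not
honey photophysics: each provenance class is a set of Gaussian band
amplitudes on realistic channel grids; one class (Mis-like) is well separated
from the reference class (BA-like), a third (Cat-like) overlaps it and is
more heterogeneous (larger per-sample band-amplitude spread, mimicking a
climatically diverse region).  Harvest seasons perturb band amplitudes
multiplicatively (batch drift), FT-MIR/NIR spectra receive per-scan
offset/gain scatter, FT-Raman spectra a broad random cubic fluorescence
baseline, and all channels white noise.

One seed stream is split into fixed-purpose substreams (drift, amplitudes,
scatter, baseline, noise, QC), so e.g. changing the replicate count cannot
change the class amplitude draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

import pandas as pd

from .spectra_io import Platform, SampleTable, SpectralBlock

__all__ = [
    "Band",
    "PlatformSpec",
    "ClassSpec",
    "GeneratorConfig",
    "SyntheticDataset",
    "default_config",
    "generate",
    "inject_qc_series",
]


@dataclass(frozen=True)
class Band:
    center: float
    width: float
    amplitude: float


@dataclass(frozen=True)
class PlatformSpec:
    platform: Platform
    axis_start: float
    axis_stop: float
    axis_step: float
    bands: tuple[Band, ...]
    # per-class relative band deviations, one value per band
    signatures: Mapping[str, tuple[float, ...]]
    replicates: int
    noise_sd: float
    gain_range: tuple[float, float]
    offset_range: tuple[float, float]
    # scales every class signature on this platform: < 1 means the platform
    # resolves the provenance classes less sharply
    signature_scale: float = 1.0
    # uniform ranges for cubic fluorescence baseline coefficients (empty = none)
    baseline_coef_ranges: tuple[tuple[float, float], ...] = ()
    # minor chemical bands: many small class-uninformative features whose
    # per-sample variation gives the spectra a realistic variance tail
    minor_bands: int = 25
    minor_amp_range: tuple[float, float] = (0.02, 0.12)
    minor_width_range: tuple[float, float] = (15.0, 50.0)
    minor_jitter_sd: float = 0.15
    # broad non-polynomial fluorescence humps (count, width range, amplitude range):
    # a low-order anchor-region correction removes these only partially
    baseline_humps: int = 0
    baseline_hump_width: tuple[float, float] = (0.15, 0.35)  # fraction of axis span
    baseline_hump_amp: tuple[float, float] = (0.0, 0.8)

    def axis(self) -> np.ndarray:
        n = int(round((self.axis_stop - self.axis_start) / self.axis_step)) + 1
        return self.axis_start + self.axis_step * np.arange(n)

    def band_matrix(self, axis: np.ndarray) -> np.ndarray:
        """(bands x channels) unit-amplitude Gaussian profiles."""
        out = np.empty((len(self.bands), axis.size))
        for i, band in enumerate(self.bands):
            out[i] = np.exp(-0.5 * ((axis - band.center) / band.width) ** 2)
        return out


@dataclass(frozen=True)
class ClassSpec:
    separation: float  # multiplier on the platform signature
    amplitude_sd: float  # per-sample relative band-amplitude spread


@dataclass(frozen=True)
class GeneratorConfig:
    platforms: Mapping[str, PlatformSpec]
    classes: Mapping[str, ClassSpec]
    harvests: tuple[int, ...]
    n_per_class_per_harvest: int
    drift_sd: float  # per-harvest, per-band multiplicative drift
    concentration_sd: float  # per-sample global intensity spread, shared across platforms
    seed: int
    # within-class band variation is driven by a few shared compositional
    # factors (low-rank covariance, as the class-modelling step assumes),
    # plus a smaller independent per-band component
    n_factors: int = 3
    factor_weight: float = 1.0
    independent_weight: float = 0.5

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_per_class_per_harvest < 1:
            raise ValueError("n_per_class_per_harvest must be >= 1")
        for name, spec in self.platforms.items():
            if spec.noise_sd < 0:
                raise ValueError(f"platforms[{name}].noise_sd must be >= 0")
            lo, hi = spec.gain_range
            if lo <= 0 or hi <= 0:
                raise ValueError(f"platforms[{name}].gain_range must exclude 0")
            if spec.replicates < 1:
                raise ValueError(f"platforms[{name}].replicates must be >= 1")
            for cls, sig in spec.signatures.items():
                if len(sig) != len(spec.bands):
                    raise ValueError(f"platforms[{name}].signatures[{cls}] length mismatch")
        for name, spec in self.classes.items():
            if spec.amplitude_sd < 0:
                raise ValueError(f"classes[{name}].amplitude_sd must be >= 0")
        if self.drift_sd < 0:
            raise ValueError("drift_sd must be >= 0")


@dataclass
class SyntheticDataset:
    """Replicate-level blocks plus metadata and the exact config that made them."""

    blocks: dict[str, SpectralBlock]
    table: SampleTable
    config: GeneratorConfig

    def averaged(self) -> tuple[dict[str, SpectralBlock], SampleTable]:
        """Replicate-averaged blocks (one row per sample) and the matching table."""
        from .spectra_io import average_replicates

        out_blocks = {}
        out_table = None
        for name, block in self.blocks.items():
            out_blocks[name], out_table = average_replicates(block, self.table)
        return out_blocks, out_table


# ---------------------------------------------------------------------------
# Defaults: the study conditions


# Each platform senses a different projection of the same chemical
# differences, so the per-platform signatures share magnitude but not
# pattern; Cat sits partway between BA and Mis with a sideways offset, so
# both Cat pairings stay genuinely harder than BA vs Mis.
_MIS_SIGS = {
    "ftmir": (1.0, -0.8, 0.6, -1.0, 0.9, 0.4, -0.5, 0.2),
    "raman": (-0.7, 1.0, -0.9, 0.5, -0.4, 0.8, 0.6, -0.3),
    "nir": (0.4, -0.5, 1.0, 0.7, -0.9, -0.3, 0.8, -0.6),
}
_CAT_ORTH = {
    "ftmir": (0.3, 0.4, -0.2, 0.3, 0.4, -0.5, 0.2, -0.4),
    "raman": (0.4, 0.3, 0.3, -0.5, 0.2, -0.2, -0.4, 0.3),
    "nir": (-0.4, 0.2, 0.3, -0.3, 0.2, 0.5, -0.2, 0.4),
}


def _signatures(ftmir: bool = False, raman: bool = False, nir: bool = False) -> dict[str, tuple[float, ...]]:
    key = "ftmir" if ftmir else ("raman" if raman else "nir")
    mis = _MIS_SIGS[key]
    orth = _CAT_ORTH[key]
    cat = tuple(0.45 * m + 0.5 * o for m, o in zip(mis, orth))
    zero = tuple(0.0 for _ in mis)
    return {"BA": zero, "Mis": mis, "Cat": cat}


def default_config(seed: int) -> GeneratorConfig:
    """Three provenance classes, four harvests, 30 samples/class/harvest.

    BA-like vs Mis-like are well separated; Cat-like overlaps BA with a wider
    amplitude distribution.  Replicates: 3 (FT-MIR) / 2 (Raman) / 2 (NIR).
    """
    ftmir = PlatformSpec(
        platform=Platform.FTMIR, axis_start=600.0, axis_stop=4000.0, axis_step=4.0,
        bands=(
            Band(780, 30, 0.55), Band(920, 25, 0.85), Band(1055, 35, 1.00),
            Band(1150, 30, 0.70), Band(1345, 40, 0.45), Band(1640, 45, 0.50),
            Band(2930, 60, 0.35), Band(3300, 180, 0.60),
        ),
        signatures=_signatures(ftmir=True), replicates=3, noise_sd=0.001,
        gain_range=(0.90, 1.10), offset_range=(-0.04, 0.04),
    )
    raman = PlatformSpec(
        platform=Platform.RAMAN, axis_start=0.0, axis_stop=3600.0, axis_step=4.0,
        bands=(
            Band(430, 25, 0.50), Band(630, 25, 0.45), Band(850, 20, 0.80),
            Band(1060, 30, 1.00), Band(1265, 30, 0.55), Band(1460, 25, 0.65),
            Band(2910, 40, 0.90), Band(2970, 30, 0.70),
        ),
        signatures=_signatures(raman=True), replicates=2, noise_sd=0.004,
        gain_range=(0.95, 1.05), offset_range=(0.0, 0.0), signature_scale=0.6,
        baseline_coef_ranges=((0.2, 1.2), (-0.5, 2.0), (-1.0, 1.0), (-0.5, 0.5)),
        baseline_humps=2,
    )
    nir = PlatformSpec(
        platform=Platform.NIR, axis_start=400.0, axis_stop=2500.0, axis_step=2.0,
        bands=(
            Band(520, 40, 0.30), Band(590, 35, 0.25), Band(1450, 60, 0.80),
            Band(1780, 50, 0.40), Band(1930, 60, 1.00), Band(2100, 60, 0.75),
            Band(2270, 50, 0.55), Band(2350, 40, 0.45),
        ),
        signatures=_signatures(nir=True), replicates=2, noise_sd=0.002,
        gain_range=(0.85, 1.15), offset_range=(-0.06, 0.06), signature_scale=0.8,
    )
    return GeneratorConfig(
        platforms={"ftmir": ftmir, "raman": raman, "nir": nir},
        classes={
            "BA": ClassSpec(separation=0.0, amplitude_sd=0.05),
            "Mis": ClassSpec(separation=0.12, amplitude_sd=0.05),
            "Cat": ClassSpec(separation=0.12, amplitude_sd=0.12),
        },
        harvests=(2014, 2015, 2016, 2017),
        n_per_class_per_harvest=30,
        drift_sd=0.02,
        concentration_sd=0.02,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Generation


_STREAMS = ("drift", "amplitude", "scatter", "baseline", "noise", "qc")


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


def generate(config: GeneratorConfig) -> SyntheticDataset:
    """Generate the dataset; the same config is bit-identical on regeneration."""
    rng = _substreams(config.seed)
    class_names = list(config.classes)
    harvests = list(config.harvests)
    n = config.n_per_class_per_harvest

    samples = []  # (sample_id, class, harvest)
    for harvest in harvests:
        for cls in class_names:
            for i in range(n):
                samples.append((f"{cls}{str(harvest)[-2:]}-{i:02d}", cls, harvest))
    n_samples = len(samples)
    # global per-sample concentration and compositional factor scores are
    # sample properties, shared across the three platforms
    concentration = 1.0 + config.concentration_sd * rng["amplitude"].standard_normal(n_samples)
    factors = rng["amplitude"].standard_normal((n_samples, config.n_factors))

    blocks: dict[str, SpectralBlock] = {}
    for pi, (name, spec) in enumerate(config.platforms.items()):
        axis = spec.axis()
        profiles = spec.band_matrix(axis)
        n_bands = len(spec.bands)
        base = np.array([b.amplitude for b in spec.bands])
        # fixed structural constants: how each compositional factor loads on
        # this platform's bands (independent of the user seed)
        struct = np.random.default_rng(912_000 + pi)
        loadmat = struct.standard_normal((n_bands, config.n_factors))
        loadmat /= np.linalg.norm(loadmat, axis=1, keepdims=True)
        # fixed minor-band library (positions/widths/amplitudes are structural)
        span = axis[-1] - axis[0]
        minor_centers = struct.uniform(axis[0] + 0.02 * span, axis[-1] - 0.02 * span, spec.minor_bands)
        minor_widths = struct.uniform(*spec.minor_width_range, spec.minor_bands)
        minor_base = struct.uniform(*spec.minor_amp_range, spec.minor_bands)
        minor_profiles = np.exp(-0.5 * ((axis[None, :] - minor_centers[:, None]) / minor_widths[:, None]) ** 2)
        # per-harvest multiplicative band drift (shared by every sample of the harvest)
        drift = 1.0 + config.drift_sd * rng["drift"].standard_normal((len(harvests), n_bands))
        harvest_row = {h: i for i, h in enumerate(harvests)}
        indep = rng["amplitude"].standard_normal((n_samples, n_bands))
        deviation = (config.factor_weight * factors @ loadmat.T
                     + config.independent_weight * indep)
        amps = np.empty((n_samples, n_bands))
        for row, (_, cls, harvest) in enumerate(samples):
            cspec = config.classes[cls]
            signature = np.asarray(spec.signatures.get(cls, (0.0,) * n_bands))
            mean_amp = base * (1.0 + cspec.separation * spec.signature_scale * signature)
            jitter = 1.0 + cspec.amplitude_sd * deviation[row]
            amps[row] = mean_amp * drift[harvest_row[harvest]] * jitter * concentration[row]
        signal = amps @ profiles  # (samples x channels)
        if spec.minor_bands:
            minor_eps = rng["amplitude"].standard_normal((n_samples, spec.minor_bands))
            minor_amps = minor_base * (1.0 + spec.minor_jitter_sd * minor_eps) * concentration[:, None]
            signal = signal + minor_amps @ minor_profiles

        rows = np.empty((n_samples * spec.replicates, axis.size))
        keys: list[str] = []
        u = (axis - axis[0]) / (axis[-1] - axis[0])  # normalised axis for baselines
        r = 0
        for row, (sid, _, _) in enumerate(samples):
            for _rep in range(spec.replicates):
                gain = rng["scatter"].uniform(*spec.gain_range)
                offset = rng["scatter"].uniform(*spec.offset_range) if spec.offset_range != (0.0, 0.0) else 0.0
                spectrum = offset + gain * signal[row]
                if spec.baseline_coef_ranges:
                    coefs = [rng["baseline"].uniform(lo, hi) for lo, hi in spec.baseline_coef_ranges]
                    spectrum = spectrum + np.polynomial.polynomial.polyval(u, coefs)
                for _ in range(spec.baseline_humps):
                    center = rng["baseline"].uniform(0.0, 1.0)
                    width = rng["baseline"].uniform(*spec.baseline_hump_width)
                    amp = rng["baseline"].uniform(*spec.baseline_hump_amp)
                    spectrum = spectrum + amp * np.exp(-0.5 * ((u - center) / width) ** 2)
                spectrum = spectrum + spec.noise_sd * rng["noise"].standard_normal(axis.size)
                rows[r] = spectrum
                keys.append(sid)
                r += 1
        blocks[name] = SpectralBlock(platform=spec.platform, axis=axis,
                                     intensities=rows, sample_keys=keys)

    max_reps = max(spec.replicates for spec in config.platforms.values())
    records = [
        {"sample_id": sid, "class_label": cls, "harvest_year": harvest, "replicate": rep}
        for sid, cls, harvest in samples
        for rep in range(1, max_reps + 1)
    ]
    table = SampleTable(pd.DataFrame.from_records(records))
    return SyntheticDataset(blocks=blocks, table=table, config=config)


def inject_qc_series(config: GeneratorConfig, n_batches: int, drift_magnitude: float,
                     platform: str = "ftmir", n_per_batch: int = 8) -> list[SpectralBlock]:
    """Repeated scans of one fixed QC profile with per-batch band perturbations.

    ``drift_magnitude`` scales a per-batch relative band-amplitude shift;
    0 makes every batch statistically identical up to scan noise.
    """
    if n_batches < 2:
        raise ValueError("QC series needs at least two batches")
    rng = _substreams(config.seed)["qc"]
    spec = config.platforms[platform]
    axis = spec.axis()
    profiles = spec.band_matrix(axis)
    base = np.array([b.amplitude for b in spec.bands])
    pi = list(config.platforms).index(platform)
    struct = np.random.default_rng(912_000 + pi)
    struct.standard_normal((len(spec.bands), config.n_factors))  # keep draw order aligned
    span = axis[-1] - axis[0]
    minor_centers = struct.uniform(axis[0] + 0.02 * span, axis[-1] - 0.02 * span, spec.minor_bands)
    minor_widths = struct.uniform(*spec.minor_width_range, spec.minor_bands)
    minor_base = struct.uniform(*spec.minor_amp_range, spec.minor_bands)
    minor_profiles = np.exp(-0.5 * ((axis[None, :] - minor_centers[:, None]) / minor_widths[:, None]) ** 2)
    minor_signal = minor_base @ minor_profiles
    batches = []
    for j in range(n_batches):
        shift = 1.0 + drift_magnitude * rng.standard_normal(len(spec.bands))
        signal = (base * shift) @ profiles + minor_signal
        rows = np.empty((n_per_batch, axis.size))
        for i in range(n_per_batch):
            gain = rng.uniform(*spec.gain_range)
            offset = rng.uniform(*spec.offset_range) if spec.offset_range != (0.0, 0.0) else 0.0
            rows[i] = offset + gain * signal + spec.noise_sd * rng.standard_normal(axis.size)
        batches.append(SpectralBlock(platform=spec.platform, axis=axis, intensities=rows,
                                     sample_keys=[f"QC-b{j + 1}-{i + 1}" for i in range(n_per_batch)]))
    return batches
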