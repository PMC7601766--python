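"""Per-platform defaults (retained regions, optimal pipelines) and YAML config I/O.

Defaults encode the optimal pretreatments for honey fingerprints: SNV +
first-order Savitzky-Golay derivative (2nd-order polynomial, 9-point window)
+ mean centering for FT-MIR and NIR, and a 5-region cubic baseline correction
prior to SNV + mean centering for FT-Raman, together with the informative
spectral windows retained per platform.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import yaml

from .preprocess import (SNV, Autoscale, Baseline, MeanCenter, MSC, PipelineStep, SavGol)
from .spectra_io import Platform, RegionSet

__all__ = [
    "default_regions",
    "default_pipeline",
    "RAMAN_BASELINE_ANCHORS",
    "load_config",
    "pipeline_from_config",
    "regions_from_config",
]

# Retained informative windows (CO2 band, detector cut-offs and flat regions excluded)
_REGIONS = {
    Platform.FTMIR: RegionSet([(600.0, 1990.0), (2400.0, 3800.0)]),
    Platform.RAMAN: RegionSet([(0.0, 1800.0), (2500.0, 3600.0)]),
    Platform.NIR: RegionSet([(400.0, 700.0), (1300.0, 2500.0)]),
}

# Five signal-free anchor windows inside the retained Raman ranges
RAMAN_BASELINE_ANCHORS = RegionSet([
    (0.0, 60.0), (1700.0, 1800.0), (2500.0, 2580.0), (3380.0, 3480.0), (3560.0, 3600.0),
])


def default_regions(platform: "Platform | str") -> RegionSet:
    return _REGIONS[Platform(str(platform).lower()) if not isinstance(platform, Platform) else platform]


def default_pipeline(platform: "Platform | str") -> tuple[PipelineStep, ...]:
    platform = Platform(str(platform).lower()) if not isinstance(platform, Platform) else platform
    if platform is Platform.RAMAN:
        return (Baseline(RAMAN_BASELINE_ANCHORS, order=3), SNV(), MeanCenter())
    return (SNV(), SavGol(deriv=1, poly=2, window=9), MeanCenter())


# ---------------------------------------------------------------------------
# YAML configuration

_STEP_BUILDERS = {
    "snv": lambda spec: SNV(),
    "msc": lambda spec: MSC(reference=tuple(spec["reference"]) if spec.get("reference") else None),
    "savgol": lambda spec: SavGol(deriv=int(spec.get("deriv", 1)), poly=int(spec.get("poly", 2)),
                                  window=int(spec.get("window", 9))),
    "baseline": lambda spec: Baseline(RegionSet([tuple(r) for r in spec["anchors"]]),
                                      order=int(spec.get("order", 3))),
    "mean_center": lambda spec: MeanCenter(),
    "autoscale": lambda spec: Autoscale(drop_constant=bool(spec.get("drop_constant", False))),
}


def load_config(path: "str | Path") -> dict:
    with open(path) as handle:
        return yaml.safe_load(handle)


def pipeline_from_config(config: dict, platform: str) -> tuple[PipelineStep, ...]:
    """Build a pipeline from ``config['pipelines'][platform]``, a list of step specs.

    Each step spec is either a bare step name or a one-key mapping of name to
    parameters, e.g. ``[snv, {savgol: {deriv: 1, poly: 2, window: 9}}, mean_center]``.
    """
    entries: Sequence = config["pipelines"][platform]
    steps = []
    for entry in entries:
        if isinstance(entry, str):
            name, params = entry, {}
        else:
            (name, params), = entry.items()
            params = params or {}
        name = name.lower()
        if name not in _STEP_BUILDERS:
            raise ValueError(f"unknown pipeline step {name!r}")
        steps.append(_STEP_BUILDERS[name](params))
    return tuple(steps)


def regions_from_config(config: dict, platform: str) -> RegionSet:
    return RegionSet([tuple(r) for r in config["regions"][platform]])
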