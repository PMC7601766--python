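"""Spectral matrices, sample metadata, region selection and cross-platform alignment.

A :class:`SpectralBlock` holds one platform's intensity matrix (samples x
channels) together with its channel axis (cm^-1 for FT-MIR / FT-Raman, nm for
NIR).  The axis is always stored ascending; files written by FT-IR vendor
software conventionally run descending and are re-ordered on load.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Platform",
    "SpectralBlock",
    "SampleTable",
    "RegionSet",
    "SpectraFormatError",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_sample_table",
    "write_sample_table",
    "read_jcamp",
    "select_regions",
    "average_replicates",
    "align_blocks",
    "subset_table",
]


class SpectraFormatError(ValueError):
    """Raised for malformed spectral or metadata files."""


class Platform(str, Enum):
    FTMIR = "ftmir"
    RAMAN = "raman"
    NIR = "nir"

    @property
    def units(self) -> str:
        return "nm" if self is Platform.NIR else "cm-1"


def _as_platform(platform: "Platform | str") -> Platform:
    return platform if isinstance(platform, Platform) else Platform(str(platform).lower())


@dataclass
class SpectralBlock:
    """One platform's spectra: channel axis plus a (samples x channels) matrix."""

    platform: Platform
    axis: np.ndarray
    intensities: np.ndarray
    sample_keys: list[str]

    def __post_init__(self) -> None:
        self.platform = _as_platform(self.platform)
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.sample_keys = [str(k) for k in self.sample_keys]
        if self.axis.ndim != 1:
            raise SpectraFormatError("axis must be one-dimensional")
        if np.any(np.diff(self.axis) <= 0):
            raise SpectraFormatError("axis must be strictly ascending with unique channels")
        if self.intensities.shape[1] != self.axis.size:
            raise SpectraFormatError(
                f"intensity columns ({self.intensities.shape[1]}) do not match axis length ({self.axis.size})"
            )
        if self.intensities.shape[0] != len(self.sample_keys):
            raise SpectraFormatError("row count does not match number of sample keys")
        if not np.all(np.isfinite(self.intensities)):
            raise SpectraFormatError("non-finite intensity values")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    def take(self, rows: Sequence[int]) -> "SpectralBlock":
        """Row subset / reorder by positional indices."""
        rows = list(rows)
        return replace(
            self,
            intensities=self.intensities[rows],
            sample_keys=[self.sample_keys[i] for i in rows],
        )

    def with_intensities(self, intensities: np.ndarray, axis: np.ndarray | None = None) -> "SpectralBlock":
        return replace(
            self,
            intensities=np.asarray(intensities, dtype=float),
            axis=self.axis if axis is None else np.asarray(axis, dtype=float),
        )


_TABLE_COLUMNS = ("sample_id", "class_label", "harvest_year", "replicate")


@dataclass
class SampleTable:
    """Per-sample metadata: id, provenance class, harvest year, replicate index.

    ``(sample_id, replicate)`` is the unique key; the same ``sample_id`` may
    appear once per replicate scan.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.frame.copy()
        missing = [c for c in _TABLE_COLUMNS if c not in frame.columns]
        if missing:
            raise SpectraFormatError(f"sample table missing columns: {missing}")
        frame["sample_id"] = frame["sample_id"].astype(str)
        frame["class_label"] = frame["class_label"].astype(str)
        frame["harvest_year"] = frame["harvest_year"].astype(int)
        frame["replicate"] = frame["replicate"].astype(int)
        if (frame["replicate"] < 1).any():
            raise SpectraFormatError("replicate indices must be >= 1")
        if (frame["class_label"].str.len() == 0).any():
            raise SpectraFormatError("empty class labels")
        if frame.duplicated(["sample_id", "replicate"]).any():
            raise SpectraFormatError("(sample_id, replicate) pairs must be unique")
        self.frame = frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["sample_id"]))

    def classes(self) -> list[str]:
        return sorted(self.frame["class_label"].unique())

    def years(self) -> list[int]:
        return sorted(self.frame["harvest_year"].unique())

    def per_sample(self) -> pd.DataFrame:
        """One row per sample_id (class/year must be consistent across replicates)."""
        nun = self.frame.groupby("sample_id")[["class_label", "harvest_year"]].nunique()
        bad = nun[(nun > 1).any(axis=1)].index.tolist()
        if bad:
            raise SpectraFormatError(f"conflicting metadata across replicates for {bad}")
        out = self.frame.drop_duplicates("sample_id").copy()
        out["replicate"] = 1
        return out.reset_index(drop=True)


@dataclass(frozen=True)
class RegionSet:
    """Union of closed intervals on the channel axis (same units as the platform).

    Intervals are normalised on construction: sorted, and overlapping or
    touching intervals merged, so the stored list is pairwise disjoint.
    """

    intervals: tuple[tuple[float, float], ...]

    def __init__(self, intervals: Iterable[Sequence[float]]):
        cleaned = []
        for lo, hi in intervals:
            lo, hi = float(min(lo, hi)), float(max(lo, hi))
            cleaned.append((lo, hi))
        if not cleaned:
            raise ValueError("RegionSet needs at least one interval")
        cleaned.sort()
        merged = [cleaned[0]]
        for lo, hi in cleaned[1:]:
            plo, phi = merged[-1]
            if lo <= phi:
                merged[-1] = (plo, max(phi, hi))
            else:
                merged.append((lo, hi))
        object.__setattr__(self, "intervals", tuple(merged))

    def mask(self, axis: np.ndarray) -> np.ndarray:
        axis = np.asarray(axis, dtype=float)
        mask = np.zeros(axis.shape, dtype=bool)
        for lo, hi in self.intervals:
            mask |= (axis >= lo) & (axis <= hi)
        return mask


# ---------------------------------------------------------------------------
# File I/O


def read_spectra_csv(path: "str | Path", platform: "Platform | str") -> SpectralBlock:
    """Read a wide CSV (header = channel positions, first column = sample key).

    Columns are permuted so the axis is ascending; row order is preserved.
    Duplicate sample keys are legal (replicate scans).
    """
    frame = pd.read_csv(path, index_col=0)
    try:
        axis = np.array([float(c) for c in frame.columns], dtype=float)
    except (TypeError, ValueError) as err:
        raise SpectraFormatError(f"non-numeric channel header in {path}: {err}") from None
    values = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise SpectraFormatError(f"missing or non-finite intensities in {path} (ragged rows?)")
    order = np.argsort(axis, kind="stable")
    return SpectralBlock(
        platform=_as_platform(platform),
        axis=axis[order],
        intensities=values[:, order],
        sample_keys=[str(k) for k in frame.index],
    )


def write_spectra_csv(block: SpectralBlock, path: "str | Path") -> None:
    frame = pd.DataFrame(block.intensities, index=block.sample_keys, columns=block.axis)
    frame.index.name = "sample_id"
    frame.to_csv(path)


def read_sample_table(path: "str | Path") -> SampleTable:
    return SampleTable(pd.read_csv(path))


def write_sample_table(table: SampleTable, path: "str | Path") -> None:
    table.frame.to_csv(path, index=False)


def read_jcamp(path: "str | Path", platform: "Platform | str") -> SpectralBlock:
    """Minimal JCAMP-DX reader: one spectrum per file, tabular ``(X++(Y..Y))`` data.

    Supports FIRSTX/LASTX/NPOINTS with XFACTOR/YFACTOR scaling and plain
    space-separated AFFN numerals only (no SQZ/DIF/DUP compression).
    """
    text = Path(path).read_text()
    fields: dict[str, str] = {}
    for m in re.finditer(r"^##([^=]+)=(.*)$", text, flags=re.M):
        fields[m.group(1).strip().upper().replace(" ", "")] = m.group(2).strip()
    title = fields.get("TITLE", Path(path).stem)
    xfactor = float(fields.get("XFACTOR", 1.0))
    yfactor = float(fields.get("YFACTOR", 1.0))
    m = re.search(r"^##XYDATA=\s*\(X\+\+\(Y\.\.Y\)\)\s*$(.*?)(?=^##|\Z)", text, flags=re.M | re.S)
    if m is None:
        raise SpectraFormatError(f"{path}: no (X++(Y..Y)) XYDATA block")
    ys = []
    for line in m.group(1).strip().splitlines():
        nums = line.split()
        if not nums:
            continue
        try:
            vals = [float(v) for v in nums]
        except ValueError:
            raise SpectraFormatError(f"{path}: non-numeric XYDATA line {line!r}") from None
        ys.extend(vals[1:])  # first number per line is the running X value
    n = int(fields.get("NPOINTS", len(ys)))
    if len(ys) != n:
        raise SpectraFormatError(f"{path}: NPOINTS={n} but {len(ys)} Y values read")
    firstx = float(fields["FIRSTX"]) * xfactor
    lastx = float(fields["LASTX"]) * xfactor
    axis = np.linspace(firstx, lastx, n)
    y = np.asarray(ys, dtype=float) * yfactor
    order = np.argsort(axis, kind="stable")
    return SpectralBlock(_as_platform(platform), axis[order], y[order][None, :], [title])


# ---------------------------------------------------------------------------
# Structural operations


def select_regions(block: SpectralBlock, regions: RegionSet) -> SpectralBlock:
    """Keep exactly the channels whose position lies in the union of closed intervals."""
    mask = regions.mask(block.axis)
    if not mask.any():
        raise ValueError("no channels in regions")
    return block.with_intensities(block.intensities[:, mask], axis=block.axis[mask])


def average_replicates(block: SpectralBlock, table: SampleTable) -> tuple[SpectralBlock, SampleTable]:
    """Collapse replicate scans to one row per sample by arithmetic mean.

    Replicate rows are identified by repeated sample keys; the output table
    carries one row per sample with ``replicate=1``.
    """
    known = set(table.frame["sample_id"])
    missing = [k for k in block.sample_keys if k not in known]
    if missing:
        raise ValueError(f"samples in block missing from table: {sorted(set(missing))}")
    order = list(dict.fromkeys(block.sample_keys))
    index = {k: i for i, k in enumerate(order)}
    sums = np.zeros((len(order), block.n_channels))
    counts = np.zeros(len(order))
    for row, key in enumerate(block.sample_keys):
        sums[index[key]] += block.intensities[row]
        counts[index[key]] += 1
    means = sums / counts[:, None]
    out_block = replace(block, intensities=means, sample_keys=order)
    per_sample = table.per_sample().set_index("sample_id").loc[order].reset_index()
    return out_block, SampleTable(per_sample)


def align_blocks(blocks: Sequence[SpectralBlock], table: SampleTable | None = None) -> list[SpectralBlock]:
    """Reduce all blocks to the common samples, in identical row order.

    Requires one row per sample in each block (average replicates first).
    Row order follows the first block's ordering restricted to the intersection.
    """
    if len(blocks) < 2:
        raise ValueError("alignment needs at least two blocks")
    common = set(blocks[0].sample_keys)
    for block in blocks[1:]:
        common &= set(block.sample_keys)
    if not common:
        raise ValueError("no common samples across blocks")
    order = [k for k in blocks[0].sample_keys if k in common]
    aligned = []
    for block in blocks:
        if len(set(block.sample_keys)) != len(block.sample_keys):
            raise ValueError("blocks must have one row per sample before alignment")
        pos = {k: i for i, k in enumerate(block.sample_keys)}
        aligned.append(block.take([pos[k] for k in order]))
    return aligned


def subset_table(table: SampleTable, sample_ids: Sequence[str]) -> SampleTable:
    """Restrict a per-sample table to ``sample_ids`` in the given order."""
    frame = table.frame.set_index("sample_id").loc[list(sample_ids)].reset_index()
    return SampleTable(frame)
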