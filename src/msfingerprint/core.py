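"""Core data containers for raw and gridded LC-MS runs.

An acquisition is an ordered list of centroided MS1 scans; after gridding it
becomes a dense retention-time x integer-m/z intensity matrix ("heatmap").
A stack of heatmaps on shared grids forms the dataset tensor that the
classifiers and the marker miner consume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

#: The fixed plant-part label vocabulary.
LABELS: tuple[str, ...] = ("roots", "stems", "leaves", "fruits")


class EmptyRunError(ValueError):
    """Raised when an acquisition contains no usable MS1 scans."""


class InsufficientScansError(ValueError):
    """Raised when fewer than two scans are available for interpolation."""


class GridMismatchError(ValueError):
    """Raised when samples that must share grids do not."""


@dataclass
class ScanRecord:
    """One centroided MS1 scan: retention time plus peak list.

    Parameters
    ----------
    rt : float
        Retention time in minutes (nonnegative).
    mz : ndarray
        Peak m/z values in Thomson, strictly increasing.
    intensity : ndarray
        Nonnegative peak intensities, same length as ``mz``.
    """

    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        # float dtype is preserved (float32 keeps big synthetic runs compact)
        self.mz = np.asarray(self.mz)
        self.intensity = np.asarray(self.intensity)
        if self.mz.dtype.kind != "f":
            self.mz = self.mz.astype(np.float64)
        if self.intensity.dtype.kind != "f":
            self.intensity = self.intensity.astype(np.float64)
        if self.rt < 0:
            raise ValueError(f"negative retention time: {self.rt}")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity lengths differ")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z values must be strictly increasing in a scan")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())


@dataclass
class RawRun:
    """One LC-MS acquisition with sample metadata attached."""

    sample_id: str
    specimen_id: str
    replicate: int
    label: str
    scans: list[ScanRecord]

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label {self.label!r} not in {LABELS}")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            # enforce the strictly-increasing RT invariant by sorting
            self.scans = sorted(self.scans, key=lambda s: s.rt)

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans], dtype=np.float64)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform retention-time grid, half-open: point k is t_start + k*t_step.

    Defaults span [1.5, 24.0) minutes at 0.03 min, i.e. 750 points.
    """

    t_start: float = 1.5
    t_step: float = 0.03
    n_points: int = 750

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a time grid needs at least 2 points")
        if self.t_step <= 0:
            raise ValueError("t_step must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.t_step * np.arange(self.n_points)

    @property
    def t_end(self) -> float:
        """Exclusive end of the grid."""
        return self.t_start + self.t_step * self.n_points


@dataclass(frozen=True)
class MassGrid:
    """Integer m/z bins tiling the mass axis.

    Bin ``n`` (integer m/z ``mz_first + n``) collects raw m/z ``x`` whose
    residual mass ``x - (mz_first + n)`` lies in ``[residual_low,
    residual_high)``; with the defaults that window is [-0.35, +0.65), so the
    bins tile the axis exactly once.
    """

    mz_first: int = 100
    n_bins: int = 1200
    residual_low: float = -0.35
    residual_high: float = 0.65

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("need at least one mass bin")
        if not np.isclose(self.residual_high - self.residual_low, 1.0):
            raise ValueError("residual window must have unit width")

    @property
    def mz_values(self) -> np.ndarray:
        """Integer m/z value of every bin."""
        return self.mz_first + np.arange(self.n_bins)

    def bin_index(self, mz: np.ndarray) -> np.ndarray:
        """Bin index for raw m/z values; may fall outside [0, n_bins)."""
        mz = np.asarray(mz, dtype=np.float64)
        return np.floor(mz - self.residual_low).astype(np.int64) - self.mz_first


@dataclass
class GriddedSample:
    """One sample as a dense RT x m/z heatmap on shared grids."""

    sample_id: str
    specimen_id: str
    replicate: int
    label: str
    matrix: np.ndarray
    time_grid: TimeGrid
    mass_grid: MassGrid
    parent_id: str | None = None
    provenance: str | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        expected = (self.time_grid.n_points, self.mass_grid.n_bins)
        if self.matrix.shape != expected:
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match grids {expected}"
            )
        if self.label not in LABELS:
            raise ValueError(f"label {self.label!r} not in {LABELS}")

    @property
    def group_id(self) -> str:
        """Grouping key for splits: augmented variants travel with the parent."""
        return self.specimen_id

    def with_matrix(self, matrix: np.ndarray, **changes) -> "GriddedSample":
        return replace(self, matrix=matrix, **changes)


class DatasetTensor:
    """Stack of gridded samples sharing one TimeGrid and one MassGrid."""

    def __init__(self, samples: Sequence[GriddedSample]):
        samples = list(samples)
        if samples:
            tg, mg = samples[0].time_grid, samples[0].mass_grid
            for s in samples[1:]:
                if s.time_grid != tg or s.mass_grid != mg:
                    raise GridMismatchError(
                        f"sample {s.sample_id} is on different grids"
                    )
            ids = [s.sample_id for s in samples]
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate sample_ids in tensor")
        self.samples = samples

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, i: int) -> GriddedSample:
        return self.samples[i]

    @property
    def time_grid(self) -> TimeGrid:
        return self.samples[0].time_grid

    @property
    def mass_grid(self) -> MassGrid:
        return self.samples[0].mass_grid

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.samples]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def subset(self, sample_ids: Iterable[str]) -> "DatasetTensor":
        wanted = set(sample_ids)
        return DatasetTensor([s for s in self.samples if s.sample_id in wanted])

    def unfold(self, dtype=None):
        from . import gridding

        return gridding.unfold(self, dtype=dtype)
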