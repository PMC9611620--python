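"""Gridding: map irregular raw scans onto shared uniform RT and m/z grids.

The mass axis is unified by summing each scan's intensities into integer-m/z
bins via a fixed residual-mass window; the time axis is unified by linear
interpolation of every mass bin's chromatogram onto a uniform grid.  The
gridded samples stack into a tensor that can be cropped to a square image or
unfolded into a samples x features matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .core import (
    DatasetTensor,
    GriddedSample,
    GridMismatchError,
    InsufficientScansError,
    MassGrid,
    RawRun,
    ScanRecord,
    TimeGrid,
)

logger = logging.getLogger(__name__)


def bin_scan(scan: ScanRecord, grid: MassGrid, out: np.ndarray | None = None) -> np.ndarray:
    """Sum one scan's intensities into integer-m/z bins.

    Each raw m/z maps to exactly one bin (the residual window is half-open
    and of unit width); signals falling off the axis are dropped and logged.
    Total binned intensity equals the total raw intensity of in-range signals.
    """
    if out is None:
        out = np.zeros(grid.n_bins, dtype=np.float64)
    idx = grid.bin_index(scan.mz)
    keep = (idx >= 0) & (idx < grid.n_bins)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.debug("bin_scan: dropped %d out-of-axis signals", n_dropped)
    np.add.at(out, idx[keep], scan.intensity[keep])
    return out


def resample_time(
    binned_scans: list[tuple[float, np.ndarray]], grid: TimeGrid
) -> np.ndarray:
    """Linearly interpolate binned scans onto a uniform time grid.

    Every mass bin is treated as an independent chromatogram.  Grid times
    outside the acquired RT range are zero-filled (no extrapolation).
    """
    if len(binned_scans) < 2:
        raise InsufficientScansError(
            f"need >= 2 scans to interpolate, got {len(binned_scans)}"
        )
    rts = np.array([rt for rt, _ in binned_scans], dtype=np.float64)
    if np.any(np.diff(rts) <= 0):
        raise ValueError("scan RTs must be strictly increasing")
    values = np.stack([v for _, v in binned_scans])  # (n_scans, n_bins)

    t = grid.times
    # index of the left bracketing scan for each grid time
    hi = np.searchsorted(rts, t, side="left")
    inside = (t >= rts[0]) & (t <= rts[-1])
    hi = np.clip(hi, 1, len(rts) - 1)
    lo = hi - 1
    w = (t - rts[lo]) / (rts[hi] - rts[lo])
    w = np.clip(w, 0.0, 1.0)[:, None]
    out = (1.0 - w) * values[lo] + w * values[hi]
    out[~inside] = 0.0
    return out


def grid_run(
    run: RawRun,
    time_grid: TimeGrid | None = None,
    mass_grid: MassGrid | None = None,
    dtype=np.float64,
) -> GriddedSample:
    """Grid one acquisition into a (n_points, n_bins) heatmap."""
    time_grid = time_grid or TimeGrid()
    mass_grid = mass_grid or MassGrid()
    binned = [(s.rt, bin_scan(s, mass_grid)) for s in run.scans]
    matrix = resample_time(binned, time_grid).astype(dtype, copy=False)
    return GriddedSample(
        sample_id=run.sample_id,
        specimen_id=run.specimen_id,
        replicate=run.replicate,
        label=run.label,
        matrix=matrix,
        time_grid=time_grid,
        mass_grid=mass_grid,
    )


def crop_square(
    sample: GriddedSample, mz_keep_low: int = 200, mz_keep_high: int = 950
) -> GriddedSample:
    """Restrict the mass axis to integer m/z in [mz_keep_low, mz_keep_high).

    With the default grids this rejects the sparse low (100-200) and high
    (950-1300) m/z regions and yields a square 750 x 750 heatmap.
    """
    mg = sample.mass_grid
    lo = mz_keep_low - mg.mz_first
    hi = mz_keep_high - mg.mz_first
    if lo < 0 or hi > mg.n_bins or lo >= hi:
        raise ValueError(
            f"crop [{mz_keep_low}, {mz_keep_high}) outside mass axis "
            f"[{mg.mz_first}, {mg.mz_first + mg.n_bins})"
        )
    new_grid = replace(mg, mz_first=mz_keep_low, n_bins=hi - lo)
    return sample.with_matrix(sample.matrix[:, lo:hi], mass_grid=new_grid)


def crop_tensor(
    tensor: DatasetTensor, mz_keep_low: int = 200, mz_keep_high: int = 950
) -> DatasetTensor:
    return DatasetTensor([crop_square(s, mz_keep_low, mz_keep_high) for s in tensor])


@dataclass(frozen=True)
class FeatureIndexMap:
    """Invertible map between flat feature indices and (rt_index, mz_bin).

    Unfolding is RT-major: flat feature ``f = rt_index * n_bins + mz_index``.
    """

    time_grid: TimeGrid
    mass_grid: MassGrid

    @property
    def n_features(self) -> int:
        return self.time_grid.n_points * self.mass_grid.n_bins

    def to_coords(self, flat: np.ndarray):
        """flat index -> (rt_index, mz_bin_index)."""
        flat = np.asarray(flat)
        return flat // self.mass_grid.n_bins, flat % self.mass_grid.n_bins

    def to_flat(self, rt_index, mz_bin_index):
        return np.asarray(rt_index) * self.mass_grid.n_bins + np.asarray(mz_bin_index)

    def mz_of_bin(self, mz_bin_index):
        """Integer m/z value of a bin index."""
        return self.mass_grid.mz_first + np.asarray(mz_bin_index)

    def rt_minutes(self, rt_index):
        return self.time_grid.t_start + self.time_grid.t_step * np.asarray(rt_index)


def unfold(tensor: DatasetTensor, dtype=None) -> tuple[np.ndarray, FeatureIndexMap]:
    """Flatten a tensor into a samples x (J*K) matrix, RT-major."""
    if len(tensor) == 0:
        raise ValueError("cannot unfold an empty tensor")
    index_map = FeatureIndexMap(tensor.time_grid, tensor.mass_grid)
    rows = [s.matrix.ravel(order="C") for s in tensor]
    X = np.stack(rows)
    if dtype is not None:
        X = X.astype(dtype, copy=False)
    return X, index_map


def fold(X: np.ndarray, index_map: FeatureIndexMap) -> list[np.ndarray]:
    """Inverse of :func:`unfold`: recover each sample's heatmap matrix."""
    J, K = index_map.time_grid.n_points, index_map.mass_grid.n_bins
    if X.shape[1] != J * K:
        raise GridMismatchError(f"width {X.shape[1]} != {J}*{K}")
    return [row.reshape(J, K) for row in X]
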