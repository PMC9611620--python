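"""Shared fixtures: tiny deterministic runs, small grids, brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from msfingerprint import (
    DatasetTensor,
    GriddedSample,
    MassGrid,
    RawRun,
    ScanRecord,
    TimeGrid,
)

LABELS = ("roots", "stems", "leaves", "fruits")


@pytest.fixture
def small_grids():
    """A 8-point time grid and 10-bin mass grid for hand-checkable tests."""
    return TimeGrid(t_start=1.0, t_step=0.5, n_points=8), MassGrid(mz_first=100, n_bins=10)


@pytest.fixture
def tiny_run(small_grids):
    """5-scan run with a handful of peaks inside the small grids."""
    scans = [
        ScanRecord(rt=1.0, mz=[100.2, 103.0], intensity=[10.0, 5.0]),
        ScanRecord(rt=2.0, mz=[100.2, 104.5], intensity=[20.0, 8.0]),
        ScanRecord(rt=3.0, mz=[103.0], intensity=[30.0]),
        ScanRecord(rt=4.0, mz=[104.5, 108.9], intensity=[12.0, 4.0]),
        ScanRecord(rt=4.6, mz=[108.9], intensity=[2.0]),
    ]
    return RawRun(
        sample_id="t1", specimen_id="sp1", replicate=1, label="roots", scans=scans
    )


def make_sample(matrix, time_grid, mass_grid, sample_id="s", specimen_id="sp",
                label="roots", replicate=1):
    return GriddedSample(
        sample_id=sample_id,
        specimen_id=specimen_id,
        replicate=replicate,
        label=label,
        matrix=np.asarray(matrix, dtype=np.float64),
        time_grid=time_grid,
        mass_grid=mass_grid,
    )


@pytest.fixture
def mini_tensor(small_grids):
    """12 samples (4 classes x 3 specimens-or-replicates) on the small grids."""
    tg, mg = small_grids
    rng = np.random.default_rng(42)
    samples = []
    for ci, label in enumerate(LABELS):
        for k in range(3):
            m = rng.uniform(0, 10, size=(tg.n_points, mg.n_bins))
            m[2 + ci, 2 * ci] = 500.0  # a class-specific hot cell
            samples.append(
                make_sample(
                    m, tg, mg,
                    sample_id=f"{label}-{k}",
                    specimen_id=f"{label}-sp{k}",
                    label=label,
                )
            )
    return DatasetTensor(samples)


def random_run(rng, n_scans, max_peaks, mass_grid, rt_lo=1.0, rt_hi=5.0):
    """A random run whose peaks sit around the mass grid (some off-axis)."""
    rts = np.sort(rng.uniform(rt_lo, rt_hi, size=n_scans))
    while len(np.unique(rts)) < n_scans:
        rts = np.sort(rng.uniform(rt_lo, rt_hi, size=n_scans))
    lo = mass_grid.mz_first - 2
    hi = mass_grid.mz_first + mass_grid.n_bins + 2
    scans = []
    for rt in rts:
        k = rng.integers(1, max_peaks + 1)
        mz = np.sort(rng.uniform(lo, hi, size=k))
        mz = mz[np.concatenate([[True], np.diff(mz) > 1e-9])]
        scans.append(
            ScanRecord(rt=float(rt), mz=mz, intensity=rng.uniform(1, 1000, size=len(mz)))
        )
    return RawRun(sample_id="r", specimen_id="sp", replicate=1, label="stems", scans=scans)


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the vectorized implementations)


def oracle_grid_run(run, time_grid, mass_grid):
    """Nested-loop gridding: binning plus per-cell linear interpolation."""
    binned = []
    for scan in run.scans:
        vec = [0.0] * mass_grid.n_bins
        for mz, inten in zip(scan.mz.tolist(), scan.intensity.tolist()):
            b = int(math.floor(mz - mass_grid.residual_low)) - mass_grid.mz_first
            if 0 <= b < mass_grid.n_bins:
                vec[b] += inten
        binned.append((scan.rt, vec))
    rts = [rt for rt, _ in binned]
    out = np.zeros((time_grid.n_points, mass_grid.n_bins))
    for j in range(time_grid.n_points):
        t = time_grid.t_start + j * time_grid.t_step
        if t < rts[0] or t > rts[-1]:
            continue
        for i in range(len(rts) - 1):
            if rts[i] <= t <= rts[i + 1]:
                w = (t - rts[i]) / (rts[i + 1] - rts[i])
                for k in range(mass_grid.n_bins):
                    out[j, k] = (1 - w) * binned[i][1][k] + w * binned[i + 1][1][k]
                break
    return out


def oracle_linear_resample(column, new_len):
    """Pointwise linear resampling of one chromatogram to new_len samples."""
    n = len(column)
    out = []
    for i in range(new_len):
        x = i * (n - 1) / (new_len - 1)
        lo = min(int(math.floor(x)), n - 2)
        w = x - lo
        out.append((1 - w) * column[lo] + w * column[lo + 1])
    return np.array(out)
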