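"""Experiment-mimicking augmentation of LC-MS fingerprints.

Five label-preserving procedures expand each sample into a fixed family of
variants, each simulating a plausible experimental deviation:

A. whole-axis chromatogram stretching/shrinkage (pump flow-rate error),
B. gradient stretching per 50-point segment (gradient program error),
C. gradient shrinkage per segment (the mirror of B),
D. mass shifts linear in m/z applied to raw spectra (quadrupole calibration),
E. global intensity alteration (source/detector gain drift).

With the default plan every sample yields 6 + 1 + 1 + 4 + 2 = 14 variants, a
15-fold dataset expansion including the originals.  All procedures are
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DatasetTensor, GriddedSample, RawRun, ScanRecord
from .gridding import grid_run

DEFAULT_STRETCH_OFFSETS = (-30, -20, -10, 10, 20, 30)
DEFAULT_MASS_SHIFT_VARIANTS = (
    (0.1, 0.6, +1),
    (0.1, 0.6, -1),
    (0.2, 1.0, +1),
    (0.2, 1.0, -1),
)
#: anchors of the linear mass-shift ramp: the instrument scan range (Th)
MZ_ANCHOR_LOW = 100.0
MZ_ANCHOR_HIGH = 1200.0


@dataclass(frozen=True)
class AugmentationPlan:
    """Parameters of the five augmentation procedures."""

    stretch_offsets: tuple[int, ...] = DEFAULT_STRETCH_OFFSETS
    segment_len: int = 50
    segment_insert_range: tuple[int, int] = (1, 7)
    mass_shift_variants: tuple[tuple[float, float, int], ...] = DEFAULT_MASS_SHIFT_VARIANTS
    intensity_factors: tuple[float, ...] = (0.95, 1.05)
    seed: int = 0  # recorded in provenance; the default plan is deterministic

    def __post_init__(self) -> None:
        if 0 in self.stretch_offsets:
            raise ValueError("0 is the identity and is not a stretch offset")
        if any(f <= 0 for f in self.intensity_factors):
            raise ValueError("intensity factors must be positive")
        for lo, hi, sign in self.mass_shift_variants:
            if lo > hi:
                raise ValueError(f"mass shift delta_low {lo} > delta_high {hi}")
            if sign not in (-1, 1):
                raise ValueError("mass shift sign must be +1 or -1")

    @property
    def expected_multiplier(self) -> int:
        """Number of augmented variants generated per original sample."""
        return (
            len(self.stretch_offsets)
            + 2  # gradient stretch + gradient shrink
            + len(self.mass_shift_variants)
            + len(self.intensity_factors)
        )


def _linear_resample(matrix: np.ndarray, new_len: int) -> np.ndarray:
    """Resample axis 0 of a matrix to new_len points by linear interpolation."""
    n = matrix.shape[0]
    if new_len == n:
        return matrix.copy()
    if new_len < 2:
        raise ValueError("resampled chromatogram needs >= 2 points")
    x = np.linspace(0.0, n - 1.0, new_len)
    lo = np.floor(x).astype(np.int64)
    lo = np.minimum(lo, n - 2)
    w = (x - lo)[:, None]
    return (1.0 - w) * matrix[lo] + w * matrix[lo + 1]


def _canonical_length(matrix: np.ndarray, n_points: int) -> np.ndarray:
    """Truncate or zero-pad axis 0 (tail end) back to the canonical length."""
    if matrix.shape[0] >= n_points:
        return matrix[:n_points]
    pad = np.zeros((n_points - matrix.shape[0], matrix.shape[1]), dtype=matrix.dtype)
    return np.concatenate([matrix, pad], axis=0)


def stretch_rt(sample: GriddedSample, k: int) -> GriddedSample:
    """Procedure A: stretch (k>0) or shrink (k<0) every mass chromatogram.

    Each column is linearly resampled from n to n+k points, then truncated or
    zero-padded at the tail back to n; end-of-run carries the least signal
    (column re-equilibration), so the tail is the safe place to cut/pad.
    """
    n = sample.time_grid.n_points
    if abs(k) >= n:
        raise ValueError(f"|k|={abs(k)} must be < n_points={n}")
    out = _canonical_length(_linear_resample(sample.matrix, n + k), n)
    return sample.with_matrix(
        out.astype(sample.matrix.dtype, copy=False),
        sample_id=f"{sample.sample_id}::A{k:+d}",
        parent_id=sample.sample_id,
        provenance=f"stretch_rt(k={k:+d})",
    )


def _segment_schedule(n_segments: int, insert_range: tuple[int, int]) -> list[int]:
    """Points inserted/removed per segment: linear ramp over the segments."""
    lo, hi = insert_range
    if n_segments == 1:
        return [lo]
    return [
        int(np.floor(lo + (hi - lo) * s / (n_segments - 1) + 0.5))
        for s in range(n_segments)
    ]


def _gradient(sample: GriddedSample, plan: AugmentationPlan, direction: int,
              tag: str) -> GriddedSample:
    n = sample.time_grid.n_points
    seg = plan.segment_len
    if n % seg != 0:
        raise ValueError(f"n_points={n} not divisible by segment_len={seg}")
    n_segments = n // seg
    schedule = _segment_schedule(n_segments, plan.segment_insert_range)
    pieces = []
    for s in range(n_segments):
        block = sample.matrix[s * seg : (s + 1) * seg]
        pieces.append(_linear_resample(block, seg + direction * schedule[s]))
    out = _canonical_length(np.concatenate(pieces, axis=0), n)
    return sample.with_matrix(
        out.astype(sample.matrix.dtype, copy=False),
        sample_id=f"{sample.sample_id}::{tag}",
        parent_id=sample.sample_id,
        provenance=f"gradient_{'stretch' if direction > 0 else 'shrink'}"
        f"(segment_len={seg}, ramp={plan.segment_insert_range})",
    )


def gradient_stretch(sample: GriddedSample, plan: AugmentationPlan | None = None) -> GriddedSample:
    """Procedure B: per-segment stretching with a 1->7 point ramp."""
    return _gradient(sample, plan or AugmentationPlan(), +1, "B")


def gradient_shrink(sample: GriddedSample, plan: AugmentationPlan | None = None) -> GriddedSample:
    """Procedure C: per-segment shrinkage with a 1->7 point ramp."""
    return _gradient(sample, plan or AugmentationPlan(), -1, "C")


def mass_shift(
    run: RawRun,
    delta_low: float,
    delta_high: float,
    sign: int,
    mz_anchor_low: float = MZ_ANCHOR_LOW,
    mz_anchor_high: float = MZ_ANCHOR_HIGH,
) -> RawRun:
    """Procedure D: shift every raw m/z by a delta linear in m/z.

    Delta ramps from ``delta_low`` at the low end of the instrument scan range
    to ``delta_high`` at the high end; intensities are untouched.  The shifted
    run is re-gridded downstream.
    """
    if delta_low > delta_high:
        raise ValueError("delta_low must be <= delta_high")
    span = mz_anchor_high - mz_anchor_low
    scans = []
    for s in run.scans:
        delta = delta_low + (delta_high - delta_low) * (s.mz - mz_anchor_low) / span
        scans.append(ScanRecord(rt=s.rt, mz=s.mz + sign * delta, intensity=s.intensity))
    return RawRun(
        sample_id=run.sample_id,
        specimen_id=run.specimen_id,
        replicate=run.replicate,
        label=run.label,
        scans=scans,
    )


def alter_intensity(sample: GriddedSample, factor: float) -> GriddedSample:
    """Procedure E: scale every intensity by a positive factor."""
    if factor <= 0:
        raise ValueError("intensity factor must be positive")
    return sample.with_matrix(
        sample.matrix * factor,
        sample_id=f"{sample.sample_id}::E{factor:g}",
        parent_id=sample.sample_id,
        provenance=f"alter_intensity(factor={factor:g})",
    )


def augment_sample(
    sample: GriddedSample, run: RawRun, plan: AugmentationPlan
) -> list[GriddedSample]:
    """All variants of one sample under the plan (14 with defaults)."""
    if run.sample_id != sample.sample_id:
        raise ValueError(
            f"run {run.sample_id!r} does not match sample {sample.sample_id!r}"
        )
    variants = [stretch_rt(sample, k) for k in plan.stretch_offsets]
    variants.append(gradient_stretch(sample, plan))
    variants.append(gradient_shrink(sample, plan))
    for i, (dlo, dhi, sign) in enumerate(plan.mass_shift_variants):
        shifted = mass_shift(run, dlo, dhi, sign)
        gridded = grid_run(
            shifted, sample.time_grid, sample.mass_grid, dtype=sample.matrix.dtype
        )
        variants.append(
            gridded.with_matrix(
                gridded.matrix,
                sample_id=f"{sample.sample_id}::D{i}",
                parent_id=sample.sample_id,
                provenance=f"mass_shift(delta_low={dlo}, delta_high={dhi}, sign={sign:+d})",
            )
        )
    for f in plan.intensity_factors:
        variants.append(alter_intensity(sample, f))
    return variants


def augment_dataset(
    runs: list[RawRun], tensor: DatasetTensor, plan: AugmentationPlan | None = None
) -> DatasetTensor:
    """Expand a tensor with every plan variant of every sample.

    ``runs`` supplies the raw data the mass-shift procedure needs; it must
    contain one run per tensor sample (matched by sample_id).
    """
    plan = plan or AugmentationPlan()
    if len(tensor) == 0:
        return DatasetTensor([])
    by_id = {r.sample_id: r for r in runs}
    missing = [s.sample_id for s in tensor if s.sample_id not in by_id]
    if missing:
        raise ValueError(f"no raw run for samples: {missing[:5]}")
    out = list(tensor.samples)
    for sample in tensor:
        out.extend(augment_sample(sample, by_id[sample.sample_id], plan))
    return DatasetTensor(out)
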