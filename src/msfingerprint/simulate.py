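"""Ground-truth-annotated synthetic LC-MS runs.

The generator emulates the statistical structure the fingerprint pipeline
assumes: centroided MS1 scans over m/z 100-1200 and RT 0-26 min containing
Gaussian chromatographic peaks with isotope envelopes, a set of background
compounds shared by all four plant-part classes, two class-unique marker
compounds per class (present at trace level elsewhere), per-replicate RT and
amplitude jitter, and an additive noise floor.  Every run is deterministic
given (seed, class, specimen, replicate), and the planted marker coordinates
are returned as ground truth so recovery can be scored end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import LABELS, GriddedSample, RawRun, ScanRecord
from .io import write_mzml  # re-exported: simulated runs serialize to mzML

__all__ = [
    "CompoundSpec",
    "ClassProfile",
    "GeneratorConfig",
    "make_default_profiles",
    "make_separable_benchmark",
    "generate_run",
    "generate_dataset",
    "write_mzml",
    "measured_snr",
]

#: isotope envelope used by default: M, M+1, M+2 at geometric-ish abundances
DEFAULT_ISOTOPES = ((0.0, 1.0), (1.0034, 0.45), (2.0068, 0.12))


@dataclass(frozen=True)
class CompoundSpec:
    """One compound: a Gaussian elution peak with an isotope envelope."""

    rt_center: float  # minutes
    rt_sigma: float  # minutes
    base_mz: float  # Th, monoisotopic signal
    amplitude: float  # apex counts of the base isotope
    isotope_pattern: tuple[tuple[float, float], ...] = DEFAULT_ISOTOPES
    adducts: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.rt_sigma <= 0:
            raise ValueError("rt_sigma must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        for _, ab in self.isotope_pattern + self.adducts:
            if not 0 < ab <= 1:
                raise ValueError("relative abundances must be in (0, 1]")

    @property
    def integer_mz(self) -> int:
        """Integer m/z bin the base isotope lands in ([-0.35, +0.65) window)."""
        return int(math.floor(self.base_mz + 0.35))


@dataclass(frozen=True)
class ClassProfile:
    """Compound inventory of one plant-part class."""

    label: str
    shared_compounds: tuple[CompoundSpec, ...]
    unique_markers: tuple[CompoundSpec, ...]
    marker_leak_factor: float = 5e-4  # out-of-class trace amplitude fraction


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs of the simulator.

    Scans cover RT 0-26 min every 0.02 min over m/z 100-1200.  RT jitter is
    kept below the 0.03-min grid step (the pipeline performs no alignment);
    extracts are prepared in triplicate.
    """

    n_specimens_per_class: int = 3
    replicates: int = 3
    scan_interval: float = 0.02  # minutes
    rt_min: float = 0.0
    rt_max: float = 26.0
    mz_min: float = 100.0
    mz_max: float = 1200.0
    rt_jitter_sd: float = 0.01  # minutes, per replicate and compound
    amplitude_jitter_cv: float = 0.1  # lognormal, per replicate and compound
    specimen_amplitude_cv: float = 0.25  # lognormal, per specimen and compound
    noise_level: float = 30.0  # counts, mean of the noise floor
    noise_sd: float = 8.0  # counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.scan_interval <= 0:
            raise ValueError("scan_interval must be positive")
        if self.noise_level < 0 or self.noise_sd < 0:
            raise ValueError("noise parameters must be nonnegative")

    @property
    def scan_times(self) -> np.ndarray:
        n = int(round((self.rt_max - self.rt_min) / self.scan_interval)) + 1
        return self.rt_min + self.scan_interval * np.arange(n)


def _separated(rt: float, mz: float, others: list[tuple[float, float]],
               min_rt: float = 0.2, min_mz: float = 3.0) -> bool:
    """True when (rt, mz) is clear of every listed compound in RT *or* m/z."""
    return all(
        abs(rt - r) > min_rt or abs(mz - m) > min_mz for r, m in others
    )


def make_default_profiles(
    seed: int = 0,
    n_shared: int = 12,
    n_markers_per_class: int = 2,
    marker_amplitude: float = 6e4,
    marker_leak_factor: float = 5e-4,
    mz_low: float = 210.0,
    mz_high: float = 930.0,
) -> list[ClassProfile]:
    """Four class profiles: shared background plus 2 unique markers per class.

    Marker amplitudes put the in-class apex far above the noise floor
    (S/N >> 10) while the leak factor keeps out-of-class traces below
    3x the mean-spectrum noise proxy.  All compound coordinates are mutually
    separated by more than the consolidation windows.  ``mz_low``/``mz_high``
    bound the compound m/z range (defaults sit inside the square crop).
    """
    rng = np.random.default_rng([seed, 777])
    taken: list[tuple[float, float]] = []

    def draw_compound(amplitude: float) -> CompoundSpec:
        while True:
            rt = float(rng.uniform(2.5, 22.0))
            mz = float(rng.uniform(mz_low, mz_high))
            if _separated(rt, mz, taken):
                taken.append((rt, mz))
                return CompoundSpec(
                    rt_center=rt,
                    rt_sigma=float(rng.uniform(0.04, 0.08)),
                    base_mz=mz,
                    amplitude=amplitude,
                )

    shared = tuple(
        draw_compound(float(np.exp(rng.uniform(np.log(3e4), np.log(3e5)))))
        for _ in range(n_shared)
    )
    profiles = []
    for label in LABELS:
        markers = tuple(
            draw_compound(marker_amplitude) for _ in range(n_markers_per_class)
        )
        profiles.append(
            ClassProfile(
                label=label,
                shared_compounds=shared,
                unique_markers=markers,
                marker_leak_factor=marker_leak_factor,
            )
        )
    return profiles


def _compound_peaks(
    compound: CompoundSpec,
    amplitude: float,
    rt_center: float,
    times: np.ndarray,
    per_scan_mz: list[list[np.ndarray]],
    per_scan_int: list[list[np.ndarray]],
) -> None:
    """Append one compound's isotope peaks to the per-scan accumulators."""
    lo = np.searchsorted(times, rt_center - 4 * compound.rt_sigma)
    hi = np.searchsorted(times, rt_center + 4 * compound.rt_sigma, side="right")
    if hi <= lo:
        return
    t = times[lo:hi]
    envelope = amplitude * np.exp(-0.5 * ((t - rt_center) / compound.rt_sigma) ** 2)
    species = compound.isotope_pattern + compound.adducts
    mzs = np.array([compound.base_mz + d for d, _ in species])
    abundances = np.array([ab for _, ab in species])
    for i, scan_idx in enumerate(range(lo, hi)):
        per_scan_mz[scan_idx].append(mzs)
        per_scan_int[scan_idx].append(envelope[i] * abundances)


def generate_run(
    profile: ClassProfile,
    specimen: int,
    replicate: int,
    config: GeneratorConfig | None = None,
    all_profiles: list[ClassProfile] | None = None,
) -> RawRun:
    """Simulate one acquisition of (specimen, replicate) from a class profile.

    When ``all_profiles`` is given, the other classes' unique markers are also
    injected at trace level (``marker_leak_factor`` of their amplitude), so
    out-of-class absence is a statistical property rather than structural.
    Replicates of one specimen share the compound inventory and specimen-level
    amplitudes; they differ only by per-replicate jitter and noise.
    """
    config = config or GeneratorConfig()
    label_idx = LABELS.index(profile.label)
    spec_rng = np.random.default_rng([config.seed, label_idx, specimen])
    rep_rng = np.random.default_rng([config.seed, label_idx, specimen, replicate])

    compounds: list[tuple[CompoundSpec, float]] = []
    sigma_s = config.specimen_amplitude_cv
    for c in profile.shared_compounds + profile.unique_markers:
        factor = float(np.exp(spec_rng.normal(0.0, sigma_s))) if sigma_s > 0 else 1.0
        compounds.append((c, c.amplitude * factor))
    if all_profiles is not None:
        for other in all_profiles:
            if other.label == profile.label:
                continue
            for m in other.unique_markers:
                compounds.append((m, m.amplitude * profile.marker_leak_factor))

    times = config.scan_times
    n_scans = len(times)
    per_scan_mz: list[list[np.ndarray]] = [[] for _ in range(n_scans)]
    per_scan_int: list[list[np.ndarray]] = [[] for _ in range(n_scans)]
    for compound, amplitude in compounds:
        rt_jit = float(rep_rng.normal(0.0, config.rt_jitter_sd))
        amp_jit = float(np.exp(rep_rng.normal(0.0, config.amplitude_jitter_cv)))
        _compound_peaks(
            compound,
            amplitude * amp_jit,
            compound.rt_center + rt_jit,
            times,
            per_scan_mz,
            per_scan_int,
        )

    # noise floor: one ion near every integer m/z in every scan, so the
    # mean-spectrum noise proxy is spatially homogeneous
    if config.noise_level > 0:
        noise_mz_grid = np.arange(
            math.ceil(config.mz_min), math.floor(config.mz_max) + 1.0
        )
        n_noise = len(noise_mz_grid)
        noise_jitter = rep_rng.uniform(-0.2, 0.2, size=(n_scans, n_noise))
        noise_int = np.abs(rep_rng.normal(config.noise_level, config.noise_sd,
                                          size=(n_scans, n_noise)))

    scans = []
    empty = np.empty(0, dtype=np.float32)
    for i in range(n_scans):
        mz_parts = list(per_scan_mz[i])
        int_parts = list(per_scan_int[i])
        if config.noise_level > 0:
            mz_parts.insert(0, noise_mz_grid + noise_jitter[i])
            int_parts.insert(0, noise_int[i])
        if not mz_parts:
            scans.append(ScanRecord(rt=float(times[i]), mz=empty, intensity=empty))
            continue
        mz = np.concatenate(mz_parts).astype(np.float32)
        intensity = np.concatenate(int_parts).astype(np.float32)
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        # merge coincident centroids (possible when a peak overlaps noise)
        dup = np.flatnonzero(np.diff(mz) <= 0)
        if dup.size:
            np.add.at(intensity, dup, intensity[dup + 1])
            keep = np.ones(len(mz), dtype=bool)
            keep[dup + 1] = False
            mz, intensity = mz[keep], intensity[keep]
        scans.append(ScanRecord(rt=float(times[i]), mz=mz, intensity=intensity))

    return RawRun(
        sample_id=f"{profile.label}-s{specimen}-r{replicate}",
        specimen_id=f"{profile.label}-s{specimen}",
        replicate=replicate,
        label=profile.label,
        scans=scans,
    )


def generate_dataset(
    config: GeneratorConfig | None = None,
    profiles: list[ClassProfile] | None = None,
) -> tuple[list[RawRun], dict[str, list[tuple[float, int]]]]:
    """All runs of a study plus the planted-marker ground truth.

    Returns ``n_specimens_per_class x 4 x replicates`` runs and a mapping
    class label -> list of (rt_center_minutes, integer m/z) of its planted
    unique markers.
    """
    config = config or GeneratorConfig()
    profiles = profiles or make_default_profiles(config.seed)
    runs = []
    for profile in profiles:
        for specimen in range(1, config.n_specimens_per_class + 1):
            for replicate in range(1, config.replicates + 1):
                runs.append(
                    generate_run(profile, specimen, replicate, config,
                                 all_profiles=profiles)
                )
    ground_truth = {
        p.label: [(m.rt_center, m.integer_mz) for m in p.unique_markers]
        for p in profiles
    }
    return runs, ground_truth


def make_separable_benchmark(
    seed: int = 0,
    n_specimens_per_class: int = 3,
    replicates: int = 3,
    mz_low: float = 210.0,
    mz_high: float = 930.0,
) -> tuple[list[RawRun], dict[str, list[tuple[float, int]]]]:
    """A cleanly separable 4-class benchmark dataset.

    Same generative structure as the defaults, but marker compounds are as
    abundant as the strongest background compounds (1.5e5 counts) and
    between-specimen amplitude variation is moderate (CV 0.1), so the classes
    are linearly separable across specimens — the property classifier sanity
    checks assume.  The leak factor is lowered to keep out-of-class traces
    under 3x the noise floor.
    """
    profiles = make_default_profiles(
        seed,
        marker_amplitude=1.5e5,
        marker_leak_factor=2e-4,
        mz_low=mz_low,
        mz_high=mz_high,
    )
    config = GeneratorConfig(
        n_specimens_per_class=n_specimens_per_class,
        replicates=replicates,
        specimen_amplitude_cv=0.1,
        amplitude_jitter_cv=0.05,
        seed=seed,
    )
    return generate_dataset(config, profiles)


def measured_snr(sample: GriddedSample, rt_index: int, mz_index: int) -> float:
    """Signal-to-noise proxy: cell intensity over the mean spectrum intensity
    at that time point (the absence rule's denominator)."""
    spectrum = sample.matrix[rt_index]
    mean = float(spectrum.mean())
    return float(spectrum[mz_index]) / mean if mean > 0 else 0.0
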