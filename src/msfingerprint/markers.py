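"""Class-unique (RT, m/z) marker extraction from linear-SVM weights.

For each class the top-weighted unfolded features are mapped back to heatmap
coordinates, kept only if the corresponding signal is absent from every
sample of the other classes (a peak is "absent" when its intensity does not
exceed ``absence_factor`` times the mean intensity of the mass spectrum at
that time point), and finally consolidated: isotopic signals at the same RT
and the same-m/z signals at neighboring time points collapse into a single
marker represented by the highest-weight member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DatasetTensor, GriddedSample
from .svm import SvmModel


@dataclass(frozen=True)
class UniquenessConfig:
    """Parameters of the ranking / absence / consolidation rules."""

    top_k: int = 2000
    absence_factor: float = 5.0
    consolidation_rt_window: int = 1  # "neighboring time points"
    isotope_mz_window: int = 2  # Da, covers M+1/M+2 isotopologues
    unique_fraction: float = 1.0  # fraction of out-class samples required absent
    use_abs_weights: bool = False
    require_in_class_presence: bool = True
    presence_fraction: float = 0.5  # fraction of in-class samples showing the peak

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.absence_factor <= 0:
            raise ValueError("absence_factor must be positive")
        if not 0 < self.unique_fraction <= 1:
            raise ValueError("unique_fraction must be in (0, 1]")
        if not 0 < self.presence_fraction <= 1:
            raise ValueError("presence_fraction must be in (0, 1]")


@dataclass
class CandidateFeature:
    """One top-ranked SVM feature mapped back to heatmap coordinates."""

    label: str
    rt_index: int
    mz_index: int
    mz: int  # integer m/z of the bin
    rt_minutes: float
    weight: float


@dataclass
class MarkerFeature:
    """A consolidated class-characteristic signal."""

    label: str
    rt_index: int
    rt_minutes: float
    mz: int
    weight: float
    members: list[CandidateFeature] = field(default_factory=list)

    @property
    def n_consolidated(self) -> int:
        return len(self.members)


def rank_class_features(
    model: SvmModel, label: str, top_k: int = 2000, use_abs_weights: bool = False
) -> list[CandidateFeature]:
    """Top-k features of one class by descending (signed) weight.

    Ties break deterministically by ascending flat feature index; top_k larger
    than the feature count returns everything.
    """
    if model.index_map is None:
        raise ValueError("model carries no feature index map")
    w = model.coef(label)
    key = np.abs(w) if use_abs_weights else w
    order = np.argsort(-key, kind="stable")[: min(top_k, w.size)]
    rt_idx, mz_idx = model.index_map.to_coords(order)
    mz = model.index_map.mz_of_bin(mz_idx)
    rt_min = model.index_map.rt_minutes(rt_idx)
    return [
        CandidateFeature(
            label=label,
            rt_index=int(rt_idx[i]),
            mz_index=int(mz_idx[i]),
            mz=int(mz[i]),
            rt_minutes=float(rt_min[i]),
            weight=float(w[order[i]]),
        )
        for i in range(len(order))
    ]


def is_peak_absent(
    sample: GriddedSample, rt_index: int, mz_index: int, absence_factor: float = 5.0
) -> bool:
    """A peak is absent when it does not exceed absence_factor x the mean
    intensity of the mass spectrum at that time point (zeros included)."""
    spectrum = sample.matrix[rt_index]
    return float(spectrum[mz_index]) <= absence_factor * float(spectrum.mean())


def filter_unique(
    candidates: list[CandidateFeature],
    tensor: DatasetTensor,
    label: str,
    config: UniquenessConfig | None = None,
) -> list[CandidateFeature]:
    """Keep candidates whose signal is absent from out-of-class samples.

    The default requires absence in *every* out-of-class sample;
    ``unique_fraction`` < 1 tolerates trace-level appearances in a minority of
    out-of-class samples.
    """
    config = config or UniquenessConfig()
    if not candidates:
        return []
    out_samples = [s for s in tensor if s.label != label]
    if not out_samples:
        return list(candidates)
    rt = np.array([c.rt_index for c in candidates])
    mz = np.array([c.mz_index for c in candidates])
    absent_counts = np.zeros(len(candidates), dtype=np.int64)
    for s in out_samples:
        mean_at_rt = s.matrix.mean(axis=1)
        intensity = s.matrix[rt, mz]
        absent_counts += intensity <= config.absence_factor * mean_at_rt[rt]
    required = config.unique_fraction * len(out_samples)
    return [c for c, n in zip(candidates, absent_counts) if n >= required]


def filter_present_in_class(
    candidates: list[CandidateFeature],
    tensor: DatasetTensor,
    label: str,
    config: UniquenessConfig | None = None,
) -> list[CandidateFeature]:
    """Keep candidates whose signal is an actual peak within the class.

    A marker must not only be absent elsewhere, it must exist in its own
    class: the signal has to exceed the absence threshold in at least
    ``presence_fraction`` of the in-class samples.  This rejects near-zero
    weight noise features when classes are in fact indistinguishable.
    """
    config = config or UniquenessConfig()
    if not candidates:
        return []
    in_samples = [s for s in tensor if s.label == label]
    if not in_samples:
        return []
    rt = np.array([c.rt_index for c in candidates])
    mz = np.array([c.mz_index for c in candidates])
    present_counts = np.zeros(len(candidates), dtype=np.int64)
    for s in in_samples:
        mean_at_rt = s.matrix.mean(axis=1)
        present_counts += s.matrix[rt, mz] > config.absence_factor * mean_at_rt[rt]
    required = config.presence_fraction * len(in_samples)
    return [c for c, n in zip(candidates, present_counts) if n >= required]


def consolidate(
    features: list[CandidateFeature],
    rt_window: int = 1,
    isotope_window: int = 2,
) -> list[MarkerFeature]:
    """Single-linkage grouping of isotope partners and RT neighbors.

    Two features link if they share the RT index and differ by at most
    ``isotope_window`` Da, or share the m/z bin and differ by at most
    ``rt_window`` time points.  Each group is represented by its
    maximum-weight member.
    """
    n = len(features)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            a, b = features[i], features[j]
            same_rt_isotope = (
                a.rt_index == b.rt_index and abs(a.mz - b.mz) <= isotope_window
            )
            same_mz_neighbor = (
                a.mz == b.mz and abs(a.rt_index - b.rt_index) <= rt_window
            )
            if same_rt_isotope or same_mz_neighbor:
                union(i, j)

    groups: dict[int, list[CandidateFeature]] = {}
    for i, f in enumerate(features):
        groups.setdefault(find(i), []).append(f)
    markers = []
    for members in groups.values():
        best = max(members, key=lambda f: f.weight)
        markers.append(
            MarkerFeature(
                label=best.label,
                rt_index=best.rt_index,
                rt_minutes=best.rt_minutes,
                mz=best.mz,
                weight=best.weight,
                members=sorted(members, key=lambda f: -f.weight),
            )
        )
    markers.sort(key=lambda m: -m.weight)
    return markers


def extract_markers(
    model: SvmModel,
    tensor: DatasetTensor,
    config: UniquenessConfig | None = None,
) -> dict[str, list[MarkerFeature]]:
    """rank -> uniqueness filter -> consolidation, per class."""
    config = config or UniquenessConfig()
    result: dict[str, list[MarkerFeature]] = {}
    for label in model.classes:
        candidates = rank_class_features(
            model, label, top_k=config.top_k, use_abs_weights=config.use_abs_weights
        )
        unique = filter_unique(candidates, tensor, label, config)
        if config.require_in_class_presence:
            unique = filter_present_in_class(unique, tensor, label, config)
        result[label] = consolidate(
            unique,
            rt_window=config.consolidation_rt_window,
            isotope_window=config.isotope_mz_window,
        )
    return result


def markers_to_table(markers: dict[str, list[MarkerFeature]]):
    """Flatten a marker dict to a pandas table (class, rt_min, mz, weight, n)."""
    import pandas as pd

    rows = [
        {
            "class": label,
            "rt_min": round(m.rt_minutes, 3),
            "mz": m.mz,
            "weight": m.weight,
            "n_consolidated": m.n_consolidated,
        }
        for label, ms in markers.items()
        for m in ms
    ]
    return pd.DataFrame(rows, columns=["class", "rt_min", "mz", "weight", "n_consolidated"])
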