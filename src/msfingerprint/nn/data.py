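"""Heatmap-to-image conversion and class-balanced sampling."""

from __future__ import annotations

import numpy as np

from ..core import GriddedSample

#: ImageNet channel statistics, the normalization the classifiers expect.
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)


def block_downscale(matrix: np.ndarray, side: int) -> np.ndarray:
    """Area-average a square matrix down to side x side.

    Block averaging (not point sampling) so that narrow chromatographic
    peaks contribute to the downscaled image instead of falling between
    sample points.  Requires the original side to be divisible by ``side``.
    """
    H, W = matrix.shape
    if H != W:
        raise ValueError(f"heatmap must be square, got {matrix.shape}")
    if H % side:
        raise ValueError(f"cannot block-average {H} down to {side}")
    f = H // side
    return matrix.reshape(side, f, side, f).mean(axis=(1, 3))


def heatmap_to_image(
    sample: GriddedSample,
    norm: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        IMAGENET_MEAN,
        IMAGENET_STD,
    ),
    downscale_to: int | None = None,
) -> np.ndarray:
    """Convert a square heatmap into a standardized 3-channel image.

    Intensities are rescaled to [0, 1] per sample, replicated to three
    channels, and channel-standardized with the configured constants
    (ImageNet statistics by default).  Returns a (3, H, W) float32 array;
    without ``downscale_to`` the spatial dims equal the input dims.
    """
    m = sample.matrix
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"heatmap must be square, got {m.shape}; crop it first")
    m = m.astype(np.float32)
    if downscale_to is not None and downscale_to != m.shape[0]:
        m = block_downscale(m, downscale_to).astype(np.float32)
    peak = float(m.max())
    if peak > 0:
        m = m / peak
    mean, std = norm
    channels = [
        (m - mean[c]) / std[c] for c in range(3)
    ]
    return np.stack(channels).astype(np.float32)


def sampling_weights(labels) -> np.ndarray:
    """Per-sample draw probabilities inversely proportional to class size.

    Expected class frequency in a batch is uniform; probabilities sum to 1.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("no samples to weight")
    classes, counts = np.unique(labels, return_counts=True)
    count_of = dict(zip(classes.tolist(), counts.tolist()))
    w = np.array([1.0 / count_of[l] for l in labels.tolist()], dtype=np.float64)
    return w / w.sum()
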