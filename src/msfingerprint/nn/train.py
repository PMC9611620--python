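"""Residual CNN (cross-entropy) and Siamese embedding network (triplet loss).

Both classifiers consume square heatmaps converted to standardized 3-channel
images.  Class imbalance is compensated by a weighted sampler that draws
training examples with probability inversely proportional to class frequency.
The Siamese network (SNN) maps samples into a 32-dimensional embedding space
trained with a batch-hard triplet loss and predicts by k-nearest-neighbor
vote against the training embeddings; its margin can be tuned by a small
model-based (Gaussian-process expected-improvement) search.

The "reduced" architecture (a short residual network over block-averaged
heatmaps) keeps training tractable on one CPU; the "full" 18-convolution
residual layout is available via ``CnnConfig(scale="full")``.  No pretrained
weights are bundled; networks train from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm as _norm

from ..core import DatasetTensor
from ..svm import ClassificationReport, score_predictions
from .data import IMAGENET_MEAN, IMAGENET_STD, heatmap_to_image, sampling_weights
from .layers import (
    Adam,
    AvgPool2d,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    ReLU,
    ResidualBlock,
    Sequential,
    calibrate_batchnorm,
    softmax_cross_entropy,
)


@dataclass(frozen=True)
class CnnConfig:
    """Architecture and input handling of the image classifier."""

    scale: str = "reduced"  # "reduced" | "full"
    input_channels: int = 3
    n_classes: int = 4
    pretrained: bool = False
    normalization: tuple = (IMAGENET_MEAN, IMAGENET_STD)
    downscale_to: int | None = 50  # block-average 750 -> 50; None keeps full size
    width: int = 8  # base channel width of the reduced network

    def __post_init__(self) -> None:
        if self.scale not in ("reduced", "full"):
            raise ValueError("scale must be 'reduced' or 'full'")
        if self.input_channels != 3:
            raise ValueError("heatmaps are replicated to 3 channels")
        if self.pretrained:
            raise ValueError(
                "no pretrained weights are bundled; networks train from scratch"
            )


@dataclass(frozen=True)
class MarginSearchConfig:
    """Model-based margin tuning over a log-uniform range."""

    trials: int = 8
    low: float = 0.05
    high: float = 5.0
    seed: int = 0


@dataclass(frozen=True)
class SnnConfig:
    backbone: CnnConfig = CnnConfig()
    embedding_dim: int = 32
    margin: float = 0.5
    k_neighbors: int = 3
    predict_rule: str = "knn"  # "knn" | "centroid"
    margin_search: MarginSearchConfig | None = None

    def __post_init__(self) -> None:
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if self.margin <= 0:
            raise ValueError("margin must be positive")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    batch_size: int = 8
    lr: float = 1e-3
    seed: int = 0
    weighted_sampling: bool = True
    device: str = "cpu"  # accepted for config compatibility; execution is CPU numpy

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.lr <= 0:
            raise ValueError("epochs, batch_size and lr must be positive")


def build_network(config: CnnConfig, n_out: int, rng: np.random.Generator) -> Sequential:
    """Assemble the residual classifier/embedder backbone."""
    w = config.width
    if config.scale == "reduced":
        return Sequential(
            [
                Conv2d(3, w, 3, rng),
                BatchNorm2d(w),
                ReLU(),
                AvgPool2d(5),
                ResidualBlock(w, w, rng),
                ResidualBlock(w, 2 * w, rng),
                AvgPool2d(2),
                GlobalAvgPool(),
                Linear(2 * w, n_out, rng),
            ]
        )
    # full: the classic 18-weighted-layer residual layout (stride-1 convs with
    # average pooling between stages)
    layers: list = [Conv2d(3, 64, 3, rng), BatchNorm2d(64), ReLU(), AvgPool2d(2)]
    widths = (64, 128, 256, 512)
    c_in = 64
    for i, c_out in enumerate(widths):
        layers += [ResidualBlock(c_in, c_out, rng), ResidualBlock(c_out, c_out, rng)]
        if i < len(widths) - 1:
            layers.append(AvgPool2d(2))
        c_in = c_out
    layers += [GlobalAvgPool(), Linear(512, n_out, rng)]
    return Sequential(layers)


def triplet_loss(anchor, positive, negative, margin: float) -> float:
    """max(0, d(a,p) - d(a,n) + margin) with Euclidean d; batch mean."""
    a = np.atleast_2d(np.asarray(anchor, dtype=np.float64))
    p = np.atleast_2d(np.asarray(positive, dtype=np.float64))
    n = np.atleast_2d(np.asarray(negative, dtype=np.float64))
    if not a.shape == p.shape == n.shape:
        raise ValueError(
            f"embedding shapes differ: {a.shape}, {p.shape}, {n.shape}"
        )
    d_ap = np.linalg.norm(a - p, axis=1)
    d_an = np.linalg.norm(a - n, axis=1)
    return float(np.maximum(0.0, d_ap - d_an + margin).mean())


def _images(tensor: DatasetTensor, ids: list[str], config: CnnConfig):
    by_id = {s.sample_id: s for s in tensor}
    X = np.stack(
        [
            heatmap_to_image(by_id[i], config.normalization, config.downscale_to)
            for i in ids
        ]
    )
    y = np.array([by_id[i].label for i in ids])
    return X, y


def _epoch_batches(rng, n, probs, batch_size):
    n_batches = max(1, int(np.ceil(n / batch_size)))
    for _ in range(n_batches):
        yield rng.choice(n, size=min(batch_size, n), replace=True, p=probs)


@dataclass
class TrainedCnn:
    """A fitted image classifier."""

    network: Sequential
    classes: list[str]
    config: CnnConfig
    train_config: TrainConfig
    final_loss: float = float("nan")

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self.network.forward(X.astype(np.float32), train=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = self.logits(X).argmax(axis=1)
        return np.array(self.classes)[idx]


def train_cnn(
    tensor: DatasetTensor,
    config: CnnConfig | None = None,
    train_config: TrainConfig | None = None,
    split: tuple[list[str], list[str]] | None = None,
) -> tuple[TrainedCnn, ClassificationReport]:
    """Train the residual CNN with cross-entropy and weighted sampling."""
    config = config or CnnConfig()
    train_config = train_config or TrainConfig()
    if split is None:
        raise ValueError("a grouped (train_ids, test_ids) split is required")
    train_ids, test_ids = split
    Xtr, ytr = _images(tensor, list(train_ids), config)
    classes = sorted(set(ytr.tolist()))
    y_idx = np.array([classes.index(l) for l in ytr])
    rng = np.random.default_rng(train_config.seed)
    net = build_network(config, len(classes), rng)
    opt = Adam(net.params(), lr=train_config.lr)
    probs = sampling_weights(ytr) if train_config.weighted_sampling else None
    loss = float("nan")
    for _ in range(train_config.epochs):
        for batch in _epoch_batches(rng, len(ytr), probs, train_config.batch_size):
            logits = net.forward(Xtr[batch], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y_idx[batch])
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
    calibrate_batchnorm(net, Xtr)
    model = TrainedCnn(net, classes, config, train_config, final_loss=loss)
    report = ClassificationReport(classes=classes)
    if test_ids:
        Xte, yte = _images(tensor, list(test_ids), config)
        report.add(score_predictions(yte, model.predict(Xte), classes))
    return model, report


def _pairwise_dist(Z: np.ndarray) -> np.ndarray:
    sq = (Z**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (Z @ Z.T)
    return np.sqrt(np.maximum(d2, 0.0) + 1e-12)


def _batch_hard_triplet(Z: np.ndarray, y: np.ndarray, margin: float):
    """Batch-hard triplet loss and its gradient w.r.t. the embeddings."""
    B = len(y)
    d = _pairwise_dist(Z)
    same = y[:, None] == y[None, :]
    eye = np.eye(B, dtype=bool)
    dZ = np.zeros_like(Z)
    losses = []
    for i in range(B):
        pos = same[i] & ~eye[i]
        neg = ~same[i]
        if not pos.any() or not neg.any():
            continue
        p = np.flatnonzero(pos)[d[i, pos].argmax()]
        n = np.flatnonzero(neg)[d[i, neg].argmin()]
        val = d[i, p] - d[i, n] + margin
        if val > 0:
            losses.append(val)
            g_ap = (Z[i] - Z[p]) / d[i, p]
            g_an = (Z[i] - Z[n]) / d[i, n]
            dZ[i] += g_ap - g_an
            dZ[p] -= g_ap
            dZ[n] += g_an
        else:
            losses.append(0.0)
    if not losses:
        return 0.0, dZ
    return float(np.mean(losses)), (dZ / len(losses)).astype(np.float32)


def knn_predict(
    train_Z: np.ndarray, train_y: np.ndarray, Z: np.ndarray, k: int = 3
) -> np.ndarray:
    """Majority vote among the k nearest training embeddings (ties -> nearest)."""
    d = np.linalg.norm(train_Z[None, :, :] - Z[:, None, :], axis=2)
    out = []
    k = min(k, len(train_y))
    for row in d:
        nearest = np.argsort(row, kind="stable")[:k]
        labels, counts = np.unique(train_y[nearest], return_counts=True)
        winners = labels[counts == counts.max()]
        if len(winners) == 1:
            out.append(winners[0])
        else:  # tie: closest neighbor among tied classes decides
            for j in nearest:
                if train_y[j] in winners:
                    out.append(train_y[j])
                    break
    return np.array(out)


@dataclass
class TrainedSnn:
    """A fitted Siamese embedder with its training reference set."""

    network: Sequential
    classes: list[str]
    config: SnnConfig
    train_config: TrainConfig
    train_embeddings: np.ndarray = None
    train_labels: np.ndarray = None
    margin_history: list = field(default_factory=list)

    @property
    def embedding_dim(self) -> int:
        return self.train_embeddings.shape[1]

    def embed(self, X: np.ndarray) -> np.ndarray:
        return self.network.forward(X.astype(np.float32), train=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self.embed(X)
        if self.config.predict_rule == "centroid":
            cents = np.stack(
                [
                    self.train_embeddings[self.train_labels == c].mean(axis=0)
                    for c in self.classes
                ]
            )
            idx = np.linalg.norm(Z[:, None, :] - cents[None], axis=2).argmin(axis=1)
            return np.array(self.classes)[idx]
        return knn_predict(
            self.train_embeddings, self.train_labels, Z, k=self.config.k_neighbors
        )


def _fit_snn(Xtr, ytr, config: SnnConfig, train_config: TrainConfig, margin: float):
    classes = sorted(set(ytr.tolist()))
    rng = np.random.default_rng(train_config.seed)
    net = build_network(config.backbone, config.embedding_dim, rng)
    opt = Adam(net.params(), lr=train_config.lr)
    probs = sampling_weights(ytr) if train_config.weighted_sampling else None
    for _ in range(train_config.epochs):
        for batch in _epoch_batches(rng, len(ytr), probs, train_config.batch_size):
            Z = net.forward(Xtr[batch], train=True)
            _, dZ = _batch_hard_triplet(Z, ytr[batch], margin)
            opt.zero_grad()
            net.backward(dZ)
            opt.step()
    calibrate_batchnorm(net, Xtr)
    return net, classes


def train_snn(
    tensor: DatasetTensor,
    config: SnnConfig | None = None,
    train_config: TrainConfig | None = None,
    split: tuple[list[str], list[str]] | None = None,
) -> tuple[TrainedSnn, ClassificationReport]:
    """Train the Siamese embedder; predict by kNN vote in embedding space.

    With ``config.margin_search`` set, the triplet margin is tuned by
    Gaussian-process expected improvement maximizing macro F1 on a grouped
    validation split carved out of the training set.
    """
    config = config or SnnConfig()
    train_config = train_config or TrainConfig()
    if split is None:
        raise ValueError("a grouped (train_ids, test_ids) split is required")
    train_ids, test_ids = split
    Xtr, ytr = _images(tensor, list(train_ids), config.backbone)
    margin = config.margin
    history: list = []
    if config.margin_search is not None:
        ms = config.margin_search
        sub = tensor.subset(train_ids)
        from ..svm import SplitPlan, grouped_split

        fit_ids, val_ids = grouped_split(
            sub, SplitPlan(train_fraction=0.75, seed=ms.seed), repeat=0
        )
        Xf, yf = _images(tensor, fit_ids, config.backbone)
        Xv, yv = _images(tensor, val_ids, config.backbone)

        def objective(m: float) -> float:
            net, classes = _fit_snn(Xf, yf, config, train_config, m)
            ztr = net.forward(Xf, train=False)
            zv = net.forward(Xv, train=False)
            pred = knn_predict(ztr, yf, zv, k=config.k_neighbors)
            return score_predictions(yv, pred, sorted(set(yf)))["macro"]["f1"]

        margin, history = search_margin(
            objective, low=ms.low, high=ms.high, n_trials=ms.trials, seed=ms.seed
        )
    net, classes = _fit_snn(Xtr, ytr, config, train_config, margin)
    model = TrainedSnn(
        network=net,
        classes=classes,
        config=replace(config, margin=margin),
        train_config=train_config,
        train_embeddings=net.forward(Xtr, train=False),
        train_labels=ytr,
        margin_history=history,
    )
    report = ClassificationReport(classes=classes)
    if test_ids:
        Xte, yte = _images(tensor, list(test_ids), config.backbone)
        report.add(score_predictions(yte, model.predict(Xte), classes))
    return model, report


def search_margin(
    objective,
    low: float = 0.05,
    high: float = 5.0,
    n_trials: int = 8,
    seed: int = 0,
) -> tuple[float, list[tuple[float, float]]]:
    """Sequential model-based maximization of ``objective`` over a log-uniform
    margin range: random warm-up, then Gaussian-process expected improvement."""
    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern, WhiteKernel

    rng = np.random.default_rng(seed)
    lo, hi = np.log(low), np.log(high)
    grid = np.linspace(lo, hi, 128)
    xs: list[float] = []
    ys: list[float] = []
    n_init = min(3, n_trials)
    for t in range(n_trials):
        if t < n_init:
            x = float(rng.uniform(lo, hi))
        else:
            import warnings

            gp = GaussianProcessRegressor(
                kernel=Matern(nu=2.5) + WhiteKernel(1e-4),
                normalize_y=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(np.array(xs)[:, None], np.array(ys))
                mu, sd = gp.predict(grid[:, None], return_std=True)
            best = max(ys)
            z = (mu - best) / np.maximum(sd, 1e-9)
            ei = (mu - best) * _norm.cdf(z) + sd * _norm.pdf(z)
            x = float(grid[int(np.argmax(ei))])
        y = float(objective(float(np.exp(x))))
        xs.append(x)
        ys.append(y)
    best_margin = float(np.exp(xs[int(np.argmax(ys))]))
    return best_margin, [(float(np.exp(a)), b) for a, b in zip(xs, ys)]
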