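"""Image conversion, balanced sampling, triplet loss, and the two networks."""

import numpy as np
import pytest

from msfingerprint import DatasetTensor, MassGrid, TimeGrid
from msfingerprint.nn import (
    Adam,
    CnnConfig,
    SnnConfig,
    TrainConfig,
    block_downscale,
    build_network,
    heatmap_to_image,
    knn_predict,
    sampling_weights,
    search_margin,
    softmax_cross_entropy,
    train_cnn,
    train_snn,
    triplet_loss,
)
from msfingerprint.nn.data import IMAGENET_MEAN, IMAGENET_STD
from msfingerprint.nn.layers import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    ReLU,
    ResidualBlock,
    Sequential,
)

from conftest import LABELS, make_sample

TG = TimeGrid(t_start=0.0, t_step=0.1, n_points=20)
MG = MassGrid(mz_first=100, n_bins=20)


def square_sample(matrix, **kw):
    return make_sample(matrix, TG, MG, **kw)


class TestHeatmapToImage:
    def test_all_zero_sample_maps_to_minus_mean_over_std(self):
        img = heatmap_to_image(square_sample(np.zeros((20, 20))))
        for c in range(3):
            expected = (0.0 - IMAGENET_MEAN[c]) / IMAGENET_STD[c]
            np.testing.assert_allclose(img[c], expected, rtol=1e-5)

    def test_max_cell_maps_to_one_minus_mean_over_std(self):
        m = np.zeros((20, 20))
        m[3, 4] = 250.0
        img = heatmap_to_image(square_sample(m))
        for c in range(3):
            expected = (1.0 - IMAGENET_MEAN[c]) / IMAGENET_STD[c]
            assert img[c, 3, 4] == pytest.approx(expected, rel=1e-5)

    def test_spatial_dims_preserved_and_3_channels(self):
        img = heatmap_to_image(square_sample(np.random.rand(20, 20)))
        assert img.shape == (3, 20, 20)

    def test_non_square_heatmap_rejected(self):
        bad = make_sample(np.zeros((20, 10)), TG, MassGrid(mz_first=100, n_bins=10))
        with pytest.raises(ValueError, match="square"):
            heatmap_to_image(bad)

    def test_block_downscale_is_area_average(self):
        m = np.arange(16.0).reshape(4, 4)
        out = block_downscale(m, 2)
        np.testing.assert_allclose(out, [[2.5, 4.5], [10.5, 12.5]])
        with pytest.raises(ValueError):
            block_downscale(m, 3)


class TestSamplingWeights:
    def test_inverse_frequency_closed_form(self):
        w = sampling_weights(["A", "A", "B"])
        np.testing.assert_allclose(w, [0.25, 0.25, 0.5])

    def test_balanced_classes_give_uniform_weights(self):
        w = sampling_weights(["A", "B", "C", "A", "B", "C"])
        np.testing.assert_allclose(w, 1 / 6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            sampling_weights([])

    def test_empirical_class_frequencies_uniform(self):
        """Monte-Carlo: each class drawn equally often within 3 SE."""
        labels = np.array(["A"] * 12 + ["B"] * 6 + ["C"] * 2)
        w = sampling_weights(labels)
        rng = np.random.default_rng(0)
        draws = rng.choice(len(labels), size=10_000, p=w)
        freq = {c: (labels[draws] == c).mean() for c in "ABC"}
        se = np.sqrt((1 / 3) * (2 / 3) / 10_000)
        for c, f in freq.items():
            assert abs(f - 1 / 3) < 3 * se


class TestTripletLoss:
    def test_satisfied_margin_gives_zero(self):
        a = np.zeros(4)
        p = np.zeros(4)
        n = np.array([2.0, 0, 0, 0])  # d(a,n) = 2 = 2 * margin
        assert triplet_loss(a, p, n, margin=1.0) == 0.0

    def test_equal_distances_give_margin(self):
        a = np.zeros(4)
        p = np.array([1.0, 0, 0, 0])
        n = np.array([0, 1.0, 0, 0])
        assert triplet_loss(a, p, n, margin=0.3) == pytest.approx(0.3)

    def test_degenerate_triplet_gives_margin(self):
        a = np.ones(8)
        assert triplet_loss(a, a, a, margin=0.5) == pytest.approx(0.5)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            triplet_loss(np.zeros(4), np.zeros(4), np.zeros(5), margin=1.0)

    def test_nonnegative_and_zero_iff_margin_met(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, p, n = rng.normal(size=(3, 6))
            margin = float(rng.uniform(0.1, 2.0))
            val = triplet_loss(a, p, n, margin)
            gap = np.linalg.norm(a - n) - np.linalg.norm(a - p)
            assert val >= 0.0
            assert (val == 0.0) == (gap >= margin)


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        """Backprop through conv/BN/residual/linear agrees with numeric grads."""
        rng = np.random.default_rng(0)
        net = Sequential(
            [
                Conv2d(3, 4, 3, rng),
                BatchNorm2d(4),
                ReLU(),
                ResidualBlock(4, 6, rng),
                GlobalAvgPool(),
                Linear(6, 3, rng),
            ]
        )
        X = rng.normal(size=(4, 3, 6, 6)).astype(np.float32)
        G = rng.normal(size=(4, 3)).astype(np.float32)

        def loss_value():
            return float((net.forward(X, train=True) * G).sum())

        loss_value()
        for p in net.params():
            p.grad[...] = 0.0
        net.forward(X, train=True)
        net.backward(G)
        # h small enough not to flip ReLU masks, large enough for float32
        h = 1e-3
        checked = 0
        for p in net.params():
            flat = p.value.reshape(-1)
            gflat = p.grad.reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                up = loss_value()
                flat[idx] = orig - h
                down = loss_value()
                flat[idx] = orig
                numeric = (up - down) / (2 * h)
                scale = max(abs(numeric), abs(gflat[idx]), 1e-2)
                assert abs(numeric - gflat[idx]) / scale < 5e-2
                checked += 1
        assert checked >= 20

    def test_single_batch_overfit(self):
        """The reduced network memorizes 8 samples within 200 steps."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(8, 3, 20, 20)).astype(np.float32)
        y = np.array([0, 1, 2, 3] * 2)
        net = build_network(CnnConfig(), 4, rng)
        opt = Adam(net.params(), lr=1e-2)
        loss = np.inf
        for _ in range(200):
            logits = net.forward(X, train=True)
            loss, d = softmax_cross_entropy(logits, y)
            opt.zero_grad()
            net.backward(d)
            opt.step()
        assert loss < 0.01


def class_image_tensor(seed=0, n_specimens=3, replicates=2, flip_labels=False):
    """20x20 squares with a class-specific bright pixel plus noise."""
    rng = np.random.default_rng(seed)
    hot = {"roots": (4, 4), "stems": (4, 14), "leaves": (14, 4), "fruits": (14, 14)}
    samples = []
    labels = []
    for label in LABELS:
        for spec in range(n_specimens):
            for rep in range(1, replicates + 1):
                m = rng.uniform(0, 1, size=(20, 20))
                r, c = hot[label]
                m[r, c] = 40.0 * float(np.exp(rng.normal(0, 0.1)))
                samples.append(
                    square_sample(
                        m,
                        sample_id=f"{label}-{spec}-{rep}",
                        specimen_id=f"{label}-{spec}",
                        label=label,
                        replicate=rep,
                    )
                )
                labels.append(label)
    if flip_labels:
        perm = rng.permutation(len(samples))
        for s, j in zip(samples, perm):
            s.label = labels[j]
    return DatasetTensor(samples)


def grouped_image_split(tensor, seed=0):
    from msfingerprint import SplitPlan, grouped_split

    return grouped_split(tensor, SplitPlan(seed=seed, stratify=True))


SMALL_CNN = CnnConfig(downscale_to=None, width=8)


class TestTrainCnn:
    def test_separable_images_classify_above_090(self):
        tensor = class_image_tensor(seed=1)
        split = grouped_image_split(tensor, seed=2)
        _, report = train_cnn(tensor, SMALL_CNN, TrainConfig(epochs=30, seed=0), split)
        assert report.macro("f1")[0] >= 0.9

    def test_permuted_labels_score_near_chance(self):
        tensor = class_image_tensor(seed=1, flip_labels=True)
        split = grouped_image_split(tensor, seed=2)
        _, report = train_cnn(tensor, SMALL_CNN, TrainConfig(epochs=20, seed=0), split)
        assert report.macro("f1")[0] <= 0.6  # hovers around 0.25

    def test_training_is_seed_deterministic(self):
        tensor = class_image_tensor(seed=1)
        split = grouped_image_split(tensor, seed=2)
        cfg = TrainConfig(epochs=5, seed=7)
        m1, r1 = train_cnn(tensor, SMALL_CNN, cfg, split)
        m2, r2 = train_cnn(tensor, SMALL_CNN, cfg, split)
        assert r1.to_json() == r2.to_json()
        np.testing.assert_array_equal(
            m1.network.params()[0].value, m2.network.params()[0].value
        )


class TestTrainSnn:
    def test_embedding_dimension_defaults_to_32(self):
        assert SnnConfig().embedding_dim == 32
        tensor = class_image_tensor(seed=1)
        split = grouped_image_split(tensor, seed=2)
        model, report = train_snn(
            tensor, SnnConfig(backbone=SMALL_CNN), TrainConfig(epochs=20, seed=0), split
        )
        assert model.embedding_dim == 32
        assert report.macro("f1")[0] >= 0.9

    def test_same_class_distances_smaller_than_cross_class(self):
        tensor = class_image_tensor(seed=4)
        split = grouped_image_split(tensor, seed=1)
        model, _ = train_snn(
            tensor, SnnConfig(backbone=SMALL_CNN), TrainConfig(epochs=20, seed=0), split
        )
        Z, y = model.train_embeddings, model.train_labels
        d = np.linalg.norm(Z[:, None, :] - Z[None, :, :], axis=2)
        same = (y[:, None] == y[None, :]) & ~np.eye(len(y), dtype=bool)
        cross = y[:, None] != y[None, :]
        assert d[same].mean() < d[cross].mean()

    def test_knn_k1_on_training_data_is_perfect(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(12, 5))
        y = np.array(list("abc") * 4)
        np.testing.assert_array_equal(knn_predict(Z, y, Z, k=1), y)

    def test_centroid_rule_available(self):
        tensor = class_image_tensor(seed=1)
        split = grouped_image_split(tensor, seed=2)
        model, _ = train_snn(
            tensor,
            SnnConfig(backbone=SMALL_CNN, predict_rule="centroid"),
            TrainConfig(epochs=10, seed=0),
            split,
        )
        preds = model.predict(
            np.stack([heatmap_to_image(s) for s in tensor.subset(split[0])])
        )
        assert set(preds) <= set(LABELS)


class TestMarginSearch:
    def test_finds_optimum_of_smooth_objective(self):
        best, history = search_margin(
            lambda m: -((np.log(m) - np.log(0.7)) ** 2), n_trials=8, seed=0
        )
        assert len(history) == 8
        assert abs(np.log(best) - np.log(0.7)) < np.log(2.0)
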