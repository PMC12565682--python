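"""Hierarchical model families: topology, handoff, freezing, capacity."""

import numpy as np
import pytest

from mvskel import nn
from mvskel.models import (
    CAE,
    HierarchicalModel,
    build_cae,
    build_l1_backbone_classifier,
    build_l1_latent_probe,
    build_l2_head,
    build_l3_head,
    build_small_backbone,
    extract_combined_features,
    reshape_dims,
    train_cae,
)
from mvskel.nn import Conv2D, Dense, FitConfig, Sequential


class TestCAEConstruction:
    def test_reference_latent_shape(self):
        cae = build_cae((224, 224, 3), (64, 128))
        assert cae.latent_shape == (56, 56, 128)

    def test_desk_scale_latent_shape(self):
        cae = build_cae((64, 64, 3), (16, 32))
        assert cae.latent_shape == (16, 16, 32)

    def test_autoencoder_round_trip_shape(self, rng):
        cae = build_cae((32, 32, 3), (8, 16))
        x = rng.random((2, 32, 32, 3)).astype(np.float32)
        assert cae.forward(x).shape == x.shape
        assert cae.encode(x).shape == (2, 8, 8, 16)

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_cae((30, 30, 3), (8, 16))

    def test_memorizes_a_single_constant_image(self):
        cae = build_cae((16, 16, 1), (4, 8), seed=1)
        X = np.full((1, 16, 16, 1), 0.5, dtype=np.float32)
        train_cae(cae, X, FitConfig(learning_rate=0.02, epochs=120,
                                    patience=120, batch_size=1))
        mse = float(np.mean((cae.reconstruct(X) - X) ** 2))
        assert mse < 1e-3


class TestHeads:
    def test_reshape_dims_examples(self):
        assert reshape_dims(32) == (4, 4, 2)
        assert reshape_dims(64) == (8, 8, 1)
        with pytest.raises(ValueError):
            reshape_dims(7)

    def test_l1_backbone_head_gap_width(self, rng):
        head = build_l1_backbone_classifier(1024)
        feats = rng.random((2, 7, 7, 1024)).astype(np.float32)
        out = head.forward(feats)
        assert out.shape == (2, 1)
        assert np.all((out > 0) & (out < 1))

    def test_zero_weight_head_outputs_half(self, rng):
        head = build_l1_backbone_classifier(16)
        for layer in head.layers:
            for p in layer.params():
                p[...] = 0.0
        out = head.forward(rng.random((3, 4, 4, 16)).astype(np.float32))
        assert np.allclose(out, 0.5)

    def test_backbone_l2_head_is_convolutional_with_three_outputs(self, rng):
        head = build_l2_head(32, "backbone")
        assert any(isinstance(l, Conv2D) for l in head.layers)
        out = head.forward(rng.random((4, 32)).astype(np.float32))
        assert out.shape == (4, 3)

    def test_cae_l2_head_has_no_convolution(self, rng):
        head = build_l2_head(8 * 8 * 16, "cae")
        assert not any(isinstance(l, Conv2D) for l in head.layers)
        out = head.forward(rng.random((4, 8, 8, 16)).astype(np.float32))
        assert out.shape == (4, 3)

    def test_l3_head_outputs_ten(self, rng):
        for family, width in (("backbone", 32), ("cae", 64)):
            head = build_l3_head(width, family)
            out = head.forward(rng.random((2, width)).astype(np.float32))
            assert out.shape == (2, 10)
            assert np.all((out > 0) & (out < 1))

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            build_l2_head(32, "transformer")


class TestCombinedFeatures:
    def test_identical_views_give_identical_blocks(self, rng):
        bb = build_small_backbone(1, (4, 8), seed=0)
        x = rng.random((2, 16, 16, 1)).astype(np.float32)
        feats = extract_combined_features(x, x, bb)
        c = feats.shape[-1]
        assert np.array_equal(feats[..., : c // 2], feats[..., c // 2:])

    def test_channel_count_is_sum(self, rng):
        bb = build_small_backbone(1, (4, 8), seed=0)
        dv = rng.random((2, 16, 16, 1)).astype(np.float32)
        lat = rng.random((2, 16, 16, 1)).astype(np.float32)
        single = bb.forward(dv)
        assert extract_combined_features(dv, lat, bb).shape[-1] == 2 * single.shape[-1]

    def test_swapping_views_permutes_blocks(self, rng):
        bb = build_small_backbone(1, (4, 8), seed=0)
        dv = rng.random((2, 16, 16, 1)).astype(np.float32)
        lat = rng.random((2, 16, 16, 1)).astype(np.float32)
        a = extract_combined_features(dv, lat, bb)
        b = extract_combined_features(lat, dv, bb)
        c = a.shape[-1] // 2
        assert np.array_equal(a[..., :c], b[..., c:])
        assert np.array_equal(a[..., c:], b[..., :c])


def _train_tiny_hierarchy(family, dataset, taxonomy, epochs=8):
    X = dataset.X
    y1 = np.array([1.0 if lab.l1 == "abnormal" else 0.0 for lab in dataset.labels])
    Y = dataset.label_matrix.astype(np.float64)
    n = len(X)
    tr, va = np.arange(0, int(0.8 * n)), np.arange(int(0.8 * n), n)
    model = HierarchicalModel(family, X.shape[1:], taxonomy, seed=0,
                              cae_filters=(8, 16), backbone_filters=(4, 8))
    cfg = FitConfig(learning_rate=2e-3, epochs=epochs, patience=epochs, seed=0)
    model.train_level(1, X[tr], y1[tr], X[va], y1[va], cfg, recon_config=cfg)
    ab_tr, ab_va = tr[y1[tr] == 1], va[y1[va] == 1]
    if len(ab_va) == 0:
        ab_va = ab_tr[:2]
    model.train_level(2, X[ab_tr], Y[ab_tr, :3], X[ab_va], Y[ab_va, :3], cfg)
    model.train_level(3, X[ab_tr], Y[ab_tr, 3:], X[ab_va], Y[ab_va, 3:], cfg)
    return model, X


@pytest.fixture(scope="module", params=["cae", "backbone"])
def trained(request, small_dataset, taxonomy):
    return _train_tiny_hierarchy(request.param, small_dataset, taxonomy)


class TestHierarchy:
    def test_levels_must_train_in_order(self, small_dataset, taxonomy):
        X = small_dataset.X
        model = HierarchicalModel("cae", X.shape[1:], taxonomy,
                                  cae_filters=(8, 16))
        with pytest.raises(RuntimeError, match="trained before"):
            model.train_level(2, X[:4], np.zeros((4, 3)), X[4:6],
                              np.zeros((2, 3)), FitConfig())

    def test_untrained_model_cannot_predict(self, small_dataset, taxonomy):
        model = HierarchicalModel("cae", small_dataset.X.shape[1:], taxonomy,
                                  cae_filters=(8, 16))
        with pytest.raises(RuntimeError, match="not fully trained"):
            model.predict_hierarchy(small_dataset.X[:2])

    def test_prediction_shapes_and_ranges(self, trained):
        model, X = trained
        p1, p2, p3 = model.predict_hierarchy(X[:5])
        assert p1.shape == (5,) and p2.shape == (5, 3) and p3.shape == (5, 10)
        for p in (p1, p2, p3):
            assert np.all((p > 0) & (p < 1))
        assert model.predict_label_vector(X[:5]).shape == (5, 13)

    def test_prediction_deterministic(self, trained):
        model, X = trained
        a = model.predict_hierarchy(X[:3])
        b = model.predict_hierarchy(X[:3])
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_lower_levels_frozen_bit_exact(self, small_dataset, taxonomy):
        X = small_dataset.X
        y1 = np.array([1.0 if lab.l1 == "abnormal" else 0.0
                       for lab in small_dataset.labels])
        Y = small_dataset.label_matrix.astype(np.float64)
        model = HierarchicalModel("cae", X.shape[1:], taxonomy, seed=0,
                                  cae_filters=(8, 16))
        cfg = FitConfig(learning_rate=2e-3, epochs=3, patience=3, seed=0)
        tr, va = np.arange(30), np.arange(30, 40)
        model.train_level(1, X[tr], y1[tr], X[va], y1[va], cfg, recon_config=cfg)
        ab = tr[y1[tr] == 1]
        ab_va = va[y1[va] == 1]
        model.train_level(2, X[ab], Y[ab, :3], X[ab_va], Y[ab_va, :3], cfg)
        enc_before = [p.copy() for p in model.trunk.encoder.all_params()]
        l2_before = [p.copy() for p in model.l2_head.all_params()]
        model.train_level(3, X[ab], Y[ab, 3:], X[ab_va], Y[ab_va, 3:], cfg)
        for a, b in zip(enc_before, model.trunk.encoder.all_params()):
            assert np.array_equal(a, b)
        for a, b in zip(l2_before, model.l2_head.all_params()):
            assert np.array_equal(a, b)

    def test_feature_handoff_tracks_trunk_weights(self, trained):
        # L2 inputs must be recomputed from the live trunk, never cached
        model, X = trained
        feats_a = model.level_features(2, X[:3])
        trunk_params = (model.trunk.encoder.all_params()
                        if model.family == "cae" else model.trunk.all_params())
        saved = trunk_params[0].copy()
        trunk_params[0][...] += 0.05
        feats_b = model.level_features(2, X[:3])
        trunk_params[0][...] = saved
        feats_c = model.level_features(2, X[:3])
        assert not np.array_equal(feats_a, feats_b)
        assert np.array_equal(feats_a, feats_c)

    def test_save_load_round_trip(self, trained, tmp_path, taxonomy):
        model, X = trained
        path = tmp_path / "model.npz"
        model.save(path)
        clone = HierarchicalModel.load(path, taxonomy)
        for a, b in zip(model.predict_hierarchy(X[:4]),
                        clone.predict_hierarchy(X[:4])):
            assert np.allclose(a, b, atol=1e-6)

    def test_l1_capacity_on_separable_fixture(self, taxonomy):
        # bright-top vs bright-bottom images are linearly separable
        rng = np.random.default_rng(0)
        n = 48
        X = rng.random((n, 16, 16, 1)).astype(np.float32) * 0.1
        y = (np.arange(n) % 2).astype(np.float64)
        X[y == 1, :8] += 0.8
        X[y == 0, 8:] += 0.8
        model = HierarchicalModel("backbone", (16, 16, 1), taxonomy,
                                  backbone_filters=(4, 8), seed=0)
        cfg = FitConfig(learning_rate=3e-3, epochs=25, patience=25, seed=0)
        model.train_level(1, X, y, X, y, cfg)
        feats = model.level_features(1, X)
        p1 = model.l1_head.forward(feats).ravel()
        from mvskel.evaluation import roc_auc
        assert roc_auc(p1, y.astype(int)) > 0.95

    def test_cae_training_loss_decreases_early(self, small_dataset):
        cae = build_cae((32, 32, 3), (8, 16), seed=0)
        hist = train_cae(cae, small_dataset.X[:30],
                         FitConfig(learning_rate=2e-3, epochs=6, patience=6,
                                   batch_size=8, seed=0))
        assert all(b < a for a, b in zip(hist.train_loss, hist.train_loss[1:]))
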