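"""Multiview composite construction: filtering, means, edges, stacking."""

import numpy as np
import pandas as pd
import pytest

from mvskel.curation import (
    CurationConfig,
    ImageRecord,
    blend_edges,
    canny_edge_map,
    clean_edge_map,
    compose_multiview,
    curate_dataset,
    filter_images,
    full_body_totals,
    group_by_specimen,
    is_full_body_view,
    mean_view,
    resize_normalize,
)


def _rec(sid="S0", view="DV", pixels=None, shape=(32, 32), value=0.2):
    if pixels is None:
        pixels = np.full(shape, value)
    return ImageRecord(sid, view, pixels)


class TestFilterImages:
    def test_identical_cohort_all_kept(self):
        records = [_rec(f"S{i}") for i in range(6)]
        kept, rejected = filter_images(records)
        assert len(kept) == 6 and not rejected

    def test_intensity_outlier_rejected(self):
        records = [_rec(f"S{i}", value=0.2) for i in range(10)]
        records.append(_rec("Sx", pixels=np.ones((32, 32))))
        kept, rejected = filter_images(records, CurationConfig(intensity_k=3.0))
        assert len(rejected) == 1
        assert rejected[0]["specimen_id"] == "Sx"
        assert rejected[0]["rule"] == "intensity_outlier"

    def test_aspect_ratio_outside_band_rejected(self):
        config = CurationConfig(aspect_band=(1.5, 3.0))
        kept, rejected = filter_images([_rec(shape=(32, 32))], config)
        assert not kept
        assert rejected[0]["rule"] == "field_of_view"


class TestResizeNormalize:
    def test_constant_maps_to_zeros(self):
        out = resize_normalize(_rec(pixels=np.full((448, 448), 0.5)), 224)
        assert out.pixels.shape == (224, 224)
        assert np.all(out.pixels == 0.0)

    def test_ramp_spans_unit_range(self):
        ramp = np.tile(np.linspace(0, 1, 336), (112, 1))
        out = resize_normalize(_rec(pixels=ramp), 224)
        assert out.pixels.shape == (224, 224)
        assert out.pixels.min() == 0.0 and out.pixels.max() == 1.0

    def test_identity_resolution_preserved_up_to_resampling(self):
        img = np.random.default_rng(0).random((64, 64))
        img[0, 0], img[1, 1] = 0.0, 1.0
        out = resize_normalize(_rec(pixels=img), 64)
        assert np.allclose(out.pixels, img, atol=0.05)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            resize_normalize(_rec(pixels=np.zeros((1, 5))), 32)


class TestGrouping:
    def test_multiple_acquisitions_counted(self):
        records = [_rec("A", "DV"), _rec("A", "DV"), _rec("A", "LAT")]
        groups, excluded = group_by_specimen(records)
        assert not excluded
        assert len(groups["A"]["DV"]) == 2 and len(groups["A"]["LAT"]) == 1

    def test_missing_view_excluded_and_logged(self):
        groups, excluded = group_by_specimen([_rec("B", "DV")])
        assert "B" not in groups
        assert excluded[0]["specimen_id"] == "B"

    def test_other_views_discarded(self):
        records = [_rec("C", "DV"), _rec("C", "LAT"), _rec("C", "OTHER")]
        groups, _ = group_by_specimen(records)
        assert len(groups["C"]["DV"]) == 1 and len(groups["C"]["LAT"]) == 1


class TestMeanView:
    def test_arithmetic_mean(self):
        out = mean_view([np.full((8, 8), 0.2), np.full((8, 8), 0.4)])
        assert np.allclose(out, 0.3)

    def test_single_image_identity(self, rng):
        img = rng.random((8, 8))
        assert np.array_equal(mean_view([img]), img)

    def test_idempotent_on_copies(self, rng):
        img = rng.random((8, 8))
        assert np.allclose(mean_view([img] * 5), img)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="identical shapes"):
            mean_view([np.zeros((8, 8)), np.zeros((4, 4))])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_view([])


class TestCanny:
    def test_constant_image_has_no_edges(self):
        assert canny_edge_map(np.full((32, 32), 0.7)).sum() == 0

    def test_vertical_step_gives_single_pixel_line(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        edges = canny_edge_map(img)
        # away from the borders the response is a thin vertical line at the
        # step (the symmetric gradient can keep both tied maxima per row)
        interior = edges[4:-4]
        row_counts = interior.sum(axis=1)
        assert np.all((row_counts >= 1) & (row_counts <= 2))
        cols = np.argwhere(interior)[:, 1]
        assert set(cols) <= {15, 16}

    def test_contrast_inversion_invariance(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 1.0
        assert np.array_equal(canny_edge_map(img), canny_edge_map(1.0 - img))

    def test_threshold_order_enforced(self):
        with pytest.raises(ValueError, match="low"):
            canny_edge_map(np.zeros((8, 8)), low_threshold=0.3, high_threshold=0.2)

    def test_small_component_cleaning(self):
        edges = np.zeros((32, 32))
        edges[2, 2:5] = 1.0          # 3-px speck
        edges[10, 2:30] = 1.0        # 28-px line
        cleaned = clean_edge_map(edges, min_size=10)
        assert cleaned[2, 2:5].sum() == 0
        assert cleaned[10, 2:30].sum() == 28


class TestBlend:
    def test_boundary_weight_returns_dv(self, rng):
        dv, lat = (rng.random((8, 8)) > 0.5).astype(float), np.zeros((8, 8))
        assert np.array_equal(blend_edges(dv, lat, 1.0), dv)

    def test_identical_maps_fixed_point(self, rng):
        m = (rng.random((8, 8)) > 0.5).astype(float)
        assert np.allclose(blend_edges(m, m, 0.37), m)

    def test_default_weight_arithmetic(self):
        out = blend_edges(np.ones((4, 4)), np.zeros((4, 4)), 0.6)
        assert np.allclose(out, 0.6)

    def test_bounded_by_max_for_binary_inputs(self, rng):
        dv = (rng.random((8, 8)) > 0.5).astype(float)
        lat = (rng.random((8, 8)) > 0.5).astype(float)
        out = blend_edges(dv, lat, 0.6)
        assert np.all(out <= np.maximum(dv, lat) + 1e-12)

    def test_errors(self):
        with pytest.raises(ValueError, match="shapes"):
            blend_edges(np.zeros((4, 4)), np.zeros((8, 8)))
        with pytest.raises(ValueError, match="w_dv"):
            blend_edges(np.zeros((4, 4)), np.zeros((4, 4)), 1.2)


class TestCompose:
    def test_channel_zero_is_mean_dv_bit_exact(self, rng):
        dv, lat, e = rng.random((16, 16)), rng.random((16, 16)), np.zeros((16, 16))
        comp = compose_multiview(dv, lat, e, "S1", {"DV": 2, "LAT": 1})
        assert np.array_equal(comp.channels[..., 0], dv)
        assert np.array_equal(comp.channels[..., 1], lat)
        assert comp.provenance == {"DV": 2, "LAT": 1}

    def test_out_of_range_rejected(self):
        bad = np.full((8, 8), 1.5)
        with pytest.raises(ValueError, match="range"):
            compose_multiview(bad, np.zeros((8, 8)), np.zeros((8, 8)), "S")

    def test_all_zero_composite_is_legal(self):
        comp = compose_multiview(*(np.zeros((8, 8)),) * 3, "S")
        assert comp.channels.shape == (8, 8, 3)


class TestPipeline:
    def test_repeated_single_image_specimen(self, taxonomy, rng):
        img = rng.random((48, 48))
        records = [ImageRecord("S1", v, img.copy()) for v in ("DV", "DV", "LAT")]
        ds = curate_dataset(records, taxonomy, CurationConfig(target_size=32))
        expected = resize_normalize(ImageRecord("S1", "DV", img), 32).pixels
        assert np.allclose(ds.composites[0].channels[..., 0], expected)
        assert np.allclose(ds.composites[0].channels[..., 1], expected)

    def test_deterministic(self, taxonomy, rng):
        records = [
            ImageRecord(f"S{i}", v, rng.random((40, 40)))
            for i in range(4) for v in ("DV", "LAT")
        ]
        ds1 = curate_dataset(list(records), taxonomy, CurationConfig(target_size=32))
        ds2 = curate_dataset(list(records), taxonomy, CurationConfig(target_size=32))
        for c1, c2 in zip(ds1.composites, ds2.composites):
            assert np.array_equal(c1.channels, c2.channels)

    def test_specimen_count_conservation(self, taxonomy, rng):
        records = [
            ImageRecord("A", "DV", rng.random((32, 32))),
            ImageRecord("A", "LAT", rng.random((32, 32))),
            ImageRecord("B", "DV", rng.random((32, 32))),  # missing LAT
            ImageRecord("C", "OTHER", rng.random((32, 32))),  # no full-body image
        ]
        ds = curate_dataset(records, taxonomy, CurationConfig(target_size=32))
        full_body_ids = {r.specimen_id for r in records if r.view in ("DV", "LAT")}
        assert len(ds) + len(ds.exclusions) == len(full_body_ids)

    def test_labels_follow_image_codes(self, taxonomy, rng):
        records = [
            ImageRecord("A", "DV", rng.random((32, 32)), codes=frozenset({"kyphosis"})),
            ImageRecord("A", "LAT", rng.random((32, 32))),
        ]
        ds = curate_dataset(records, taxonomy, CurationConfig(target_size=32))
        assert ds.labels[0].l1 == "abnormal"
        assert ds.labels[0].l2_set == {"Spine"}


class TestViewSelection:
    def test_full_body_labels(self):
        assert is_full_body_view("Full body-DV")
        assert is_full_body_view("full body-Lat")
        assert not is_full_body_view("Skull-DV")
        assert not is_full_body_view("Forelimbs")

    def test_totals_sum_only_full_body_rows(self):
        table = pd.DataFrame({
            "view": ["Full body-DV", "Full body-Lat", "Skull-DV"],
            "n_images": [100, 50, 10],
            "n_abnormalities": [5, 3, 1],
        })
        totals = full_body_totals(table)
        assert totals == {"n_images": 150, "n_abnormalities": 8, "n_views": 2}
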