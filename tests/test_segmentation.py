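import numpy as np
import pytest

from guvcolocal.io import ChannelSpec, FieldOfView
from guvcolocal.segmentation import (
    LabelMap,
    SegmentationParams,
    combine_role_channels,
    filter_labels,
    measure_objects,
    segment_role,
)


def render_ring(shape=(128, 128), center=(64, 64), radius=10.0, width=2.0, amplitude=1.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    d = np.hypot(rr - center[0], cc - center[1])
    return amplitude * np.exp(-((d - radius) ** 2) / (2 * width**2))


def render_disk(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (np.hypot(rr - center[0], cc - center[1]) <= radius).astype(float)


class TestSegmentRole:
    def test_blank_image_yields_no_objects(self):
        out = segment_role(np.zeros((64, 64)), "lipid", SegmentationParams())
        assert out.n_objects == 0

    def test_noise_only_image_yields_no_objects(self):
        rng = np.random.default_rng(3)
        noise = rng.normal(0.05, 0.01, (256, 256)).clip(0)
        out = segment_role(noise / noise.max(), "lipid", SegmentationParams())
        assert out.n_objects == 0

    def test_single_ring_becomes_one_filled_disk(self):
        # hard annulus with outer radius 10 and 2 px wall; the filled object
        # should recover the enclosed disk area
        rr, cc = np.mgrid[0:128, 0:128]
        d = np.hypot(rr - 64, cc - 64)
        img = ((d <= 10) & (d > 8)).astype(float)
        params = SegmentationParams(
            smoothing_radius_px=0.5,
            clahe_tile_px=0,
            hysteresis_low_fraction=1.0,
            exclude_border=False,
            split_touching=False,
        )
        out = segment_role(img, "lipid", params)
        assert out.n_objects == 1
        area = (out.grid == 1).sum()
        assert abs(area - np.pi * 100) / (np.pi * 100) < 0.10

    def test_touching_disks_split(self):
        img = render_disk((128, 128), (64, 50), 12) + render_disk((128, 128), (64, 74), 12)
        img = np.clip(img, 0, 1)
        params = SegmentationParams(split_touching=True, smoothing_radius_px=0.5)
        out = segment_role(img, "content", params)
        assert out.n_objects == 2

    def test_label_count_invariant_to_intensity_rescaling(self):
        img = render_ring() + render_ring(center=(30, 96), radius=8)
        a = segment_role(img, "lipid", SegmentationParams(exclude_border=False))
        b = segment_role(img * 37.5, "lipid", SegmentationParams(exclude_border=False))
        assert a.n_objects == b.n_objects


class TestFilterLabels:
    def test_small_object_removed_with_reason(self):
        grid = np.zeros((32, 32), dtype=np.int32)
        grid[5:8, 5] = 1  # area 3
        lm, log = filter_labels(LabelMap(grid, "lipid", 0), SegmentationParams(min_area_px=20))
        assert lm.n_objects == 0
        assert log.iloc[0]["reason"] == "area"

    def test_solid_disk_retained(self):
        grid = render_disk((64, 64), (32, 32), 10).astype(np.int32)
        lm, log = filter_labels(LabelMap(grid, "lipid", 0), SegmentationParams())
        assert lm.n_objects == 1
        assert log.empty

    def test_c_shape_removed_for_low_solidity(self):
        rr, cc = np.mgrid[0:64, 0:64]
        d = np.hypot(rr - 32, cc - 32)
        half_annulus = ((d > 8) & (d < 14) & (cc < 32)).astype(np.int32)
        lm, log = filter_labels(
            LabelMap(half_annulus, "lipid", 0), SegmentationParams(solidity_min=0.8)
        )
        assert lm.n_objects == 0
        assert log.iloc[0]["reason"] == "solidity"

    def test_border_object_removed_when_excluded(self):
        grid = np.zeros((32, 32), dtype=np.int32)
        grid[0:10, 5:15] = 1
        lm, log = filter_labels(LabelMap(grid, "lipid", 0), SegmentationParams(exclude_border=True))
        assert lm.n_objects == 0
        assert log.iloc[0]["reason"] == "border"

    def test_relabelling_is_consecutive(self):
        grid = np.zeros((64, 64), dtype=np.int32)
        grid[5:15, 5:15] = 2
        grid[30:40, 30:40] = 7
        lm, _ = filter_labels(LabelMap(grid, "lipid", 0), SegmentationParams(exclude_border=False))
        assert sorted(np.unique(lm.grid)) == [0, 1, 2]


class TestCombineRoleChannels:
    def _field(self, channels):
        return FieldOfView(0, (0, 0), channels, 1.0)

    def test_single_channel_is_normalized(self):
        specs = [ChannelSpec("a", "lipid")]
        f = self._field({"a": np.array([[0.0, 5.0], [10.0, 2.5]])})
        out = combine_role_channels(f, "lipid", specs)
        np.testing.assert_allclose(out, [[0, 0.5], [1.0, 0.25]])

    def test_blank_channel_does_not_dilute_signal(self):
        specs = [ChannelSpec("a", "lipid"), ChannelSpec("b", "lipid")]
        disk = render_disk((32, 32), (16, 16), 5)
        f = self._field({"a": np.zeros((32, 32)), "b": disk * 123.0})
        np.testing.assert_allclose(combine_role_channels(f, "lipid", specs), disk)

    def test_missing_lipid_role_is_error(self):
        specs = [ChannelSpec("a", "content"), ChannelSpec("m", "lipid")]
        f = self._field({"a": np.zeros((8, 8))})
        with pytest.raises(ValueError, match="no lipid"):
            combine_role_channels(f, "lipid", specs)


class TestMeasureObjects:
    def _setup_square(self, value=7.0):
        grid = np.zeros((32, 32), dtype=np.int32)
        grid[10:15, 10:15] = 1
        lm = LabelMap(grid, "lipid", 0)
        cm = LabelMap(np.zeros_like(grid), "content", 0)
        img = np.zeros((32, 32))
        img[grid == 1] = value
        specs = [ChannelSpec("mem", "lipid")]
        field = FieldOfView(0, (0, 0), {"mem": img}, pixel_size=1.0)
        return lm, cm, field, specs

    def test_square_area_and_equivalent_radius(self):
        lm, cm, field, specs = self._setup_square()
        rec = measure_objects(lm, cm, field, specs).iloc[0]
        assert rec["area_px"] == 25
        assert rec["equivalent_radius_um"] == pytest.approx(np.sqrt(25 / np.pi), abs=1e-12)

    def test_constant_intensity_stats_collapse(self):
        lm, cm, field, specs = self._setup_square(value=7.0)
        rec = measure_objects(lm, cm, field, specs).iloc[0]
        assert rec["mem_mean_mem"] == rec["mem_min_mem"] == rec["mem_max_mem"] == 7.0
        assert rec["mem_sum_mem"] == 7.0 * 25

    def test_disk_aspect_ratio_near_one(self):
        grid = render_disk((64, 64), (32, 32), 10).astype(np.int32)
        lm = LabelMap(grid, "lipid", 0)
        cm = LabelMap(np.zeros_like(grid), "content", 0)
        field = FieldOfView(0, (0, 0), {"mem": grid.astype(float)}, 1.0)
        rec = measure_objects(lm, cm, field, [ChannelSpec("mem", "lipid")]).iloc[0]
        assert 1.0 <= rec["aspect_ratio"] <= 1.05

    def test_content_object_matched_by_overlap_plurality(self):
        grid = np.zeros((32, 32), dtype=np.int32)
        grid[5:15, 5:15] = 1
        grid[20:30, 20:30] = 2
        content = np.zeros_like(grid)
        content[7:13, 7:13] = 1  # overlaps lipid object 1
        lm = LabelMap(grid, "lipid", 0)
        cm = LabelMap(content, "content", 0)
        img = np.ones((32, 32))
        specs = [ChannelSpec("mem", "lipid"), ChannelSpec("lum", "content")]
        field = FieldOfView(0, (0, 0), {"mem": img, "lum": img * 3}, 1.0)
        recs = measure_objects(lm, cm, field, specs)
        assert recs.loc[recs["object_id"] == 1, "content_label"].item() == 1
        assert recs.loc[recs["object_id"] == 2, "content_label"].item() == 0
        assert recs.loc[recs["object_id"] == 1, "lum_mean_lum"].item() == 3.0
        assert np.isnan(recs.loc[recs["object_id"] == 2, "lum_mean_lum"].item())

    def test_mismatched_shapes_rejected(self):
        lm, cm, field, specs = self._setup_square()
        bad = LabelMap(np.zeros((16, 16), dtype=np.int32), "content", 0)
        with pytest.raises(ValueError, match="mismatch"):
            measure_objects(lm, bad, field, specs)


class TestOnSyntheticScene:
    def test_all_clean_vesicles_detected(self, small_clean_scene, segmented_small_scene):
        _, _, _, records = segmented_small_scene
        assert len(records) == len(small_clean_scene.truth)

    def test_detected_centroids_near_truth(self, small_clean_scene, segmented_small_scene):
        _, _, _, records = segmented_small_scene
        from guvcolocal.evaluation import match_objects

        _, m = match_objects(
            small_clean_scene.truth, records, image_shape=small_clean_scene.spec.image_shape
        )
        assert m.recall == 1.0
        assert m.precision == 1.0
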