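import numpy as np
import pandas as pd
import pytest

from guvcolocal.io import AcquisitionMeta, read_dataset
from guvcolocal.synthesis import (
    MIXTURE_RATIOS,
    SceneSpec,
    TransferSimSpec,
    allocate_populations,
    default_content_exchange_layout,
    generate_dataset,
    mixture_fractions,
    render_scene,
    simulate_content_transfer,
)


class TestSceneRendering:
    def test_empty_scene_has_no_ground_truth(self, content_layout):
        channels, amounts = content_layout
        spec = SceneSpec(image_shape=(128, 128), n_vesicles=0, fractions={"P1": 1.0}, seed=0)
        scene = render_scene(spec, channels, amounts)
        assert scene.truth.empty
        assert scene.label_map.max() == 0
        assert scene.channels["rho"].mean() > 0  # background + noise still present

    def test_label_count_matches_vesicle_count(self, content_layout):
        channels, amounts = content_layout
        spec = SceneSpec(image_shape=(640, 640), n_vesicles=50, seed=1)
        scene = render_scene(spec, channels, amounts)
        assert scene.label_map.max() == 50
        assert len(scene.truth) == 50

    def test_population_determines_channel_amounts(self, content_layout):
        channels, amounts = content_layout
        spec = SceneSpec(
            image_shape=(512, 512),
            n_vesicles=30,
            fractions={"P1": 0.4, "P2": 0.3, "PC": 0.3},
            seed=2,
        )
        truth = render_scene(spec, channels, amounts).truth
        p1 = truth[truth["population"] == "P1"]
        pc = truth[truth["population"] == "PC"]
        assert (p1["amount_dexB"] == 0).all()
        assert (p1["amount_dexA"] > 0).all()
        assert (pc["amount_dexA"] > 0).all() and (pc["amount_dexB"] > 0).all()

    def test_deterministic_per_seed(self, content_layout):
        channels, amounts = content_layout
        spec = SceneSpec(image_shape=(256, 256), n_vesicles=10, seed=33)
        a = render_scene(spec, channels, amounts)
        b = render_scene(spec, channels, amounts)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        np.testing.assert_array_equal(a.channels["rho"], b.channels["rho"])

    def test_integrated_intensity_linear_in_amount(self, content_layout):
        """Pre-noise rendered mass must scale linearly with the true amount."""
        channels, amounts = content_layout
        base = SceneSpec(
            image_shape=(128, 128),
            n_vesicles=1,
            fractions={"P1": 1.0},
            amount_sigma_log=0.0,
            background=0.0,
            read_sigma=0.0,
            photon_scale=0.0,
            seed=4,
        )
        one = render_scene(base, channels, amounts)
        scaled_amounts = {"P1": {"rho": 3.0, "dexA": 3.0}}
        three = render_scene(base, channels, scaled_amounts)
        for ch in ("rho", "dexA"):
            ratio = three.channels[ch].sum() / one.channels[ch].sum()
            assert ratio == pytest.approx(3.0, rel=1e-6)

    def test_overcrowded_scene_fails_loudly(self, content_layout):
        channels, amounts = content_layout
        spec = SceneSpec(image_shape=(96, 96), n_vesicles=200, seed=0)
        with pytest.raises(RuntimeError, match="density"):
            render_scene(spec, channels, amounts)

    def test_fraction_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SceneSpec(fractions={"P1": 0.6, "P2": 0.6})


class TestPopulationAllocation:
    def test_counts_are_exact_for_round_fractions(self):
        rng = np.random.default_rng(0)
        labels = allocate_populations(1000, {"P1": 0.5, "P2": 0.3, "PC": 0.2}, rng)
        counts = pd.Series(labels).value_counts()
        assert counts["P1"] == 500 and counts["P2"] == 300 and counts["PC"] == 200

    def test_mixture_ratio_arithmetic(self):
        f = mixture_fractions(MIXTURE_RATIOS["M4"])
        assert f["PC"] == pytest.approx(0.05 / 2.05)

    def test_largest_remainder_preserves_total(self):
        rng = np.random.default_rng(1)
        labels = allocate_populations(997, mixture_fractions((1, 1, 0.1)), rng)
        assert len(labels) == 997


class TestContentTransfer:
    def test_zero_transfer_keeps_amounts(self):
        df = simulate_content_transfer(TransferSimSpec(n_pairs=100, transfer_high=0.0, seed=0))
        assert (df["marker1"] + df["marker2"] > 0).all()
        p1 = df[df["partner"] == 1]
        assert (p1["marker1"] == 1.0).all()
        assert (p1["marker2"] == 0.0).all()

    def test_full_transfer_swaps_markers(self):
        df = simulate_content_transfer(
            TransferSimSpec(n_pairs=50, transfer_low=1.0, transfer_high=1.0, seed=0)
        )
        p1 = df[df["partner"] == 1]
        assert (p1["marker1"] == 0.0).all()
        assert (p1["marker2"] == 1.0).all()

    def test_marker_totals_conserved_per_pair(self):
        spec = TransferSimSpec(n_pairs=2000, amount_marker1=2.5, amount_marker2=0.7, seed=5)
        df = simulate_content_transfer(spec)
        per_pair = df.groupby("pair_id")[["marker1", "marker2"]].sum()
        np.testing.assert_allclose(per_pair["marker1"], 2.5, rtol=0, atol=1e-12)
        np.testing.assert_allclose(per_pair["marker2"], 0.7, rtol=0, atol=1e-12)

    def test_exchanged_vesicles_anticorrelated(self):
        df = simulate_content_transfer(TransferSimSpec(n_pairs=5000, seed=11))
        ex = df[df["exchanged"]]
        r = np.corrcoef(ex["marker1"], ex["marker2"])[0, 1]
        assert r < -0.5

    def test_partial_exchange_labels(self):
        df = simulate_content_transfer(TransferSimSpec(n_pairs=4000, p_exchanged=0.25, seed=2))
        frac = df["exchanged"].mean()
        assert frac == pytest.approx(0.25, abs=3 * np.sqrt(0.25 * 0.75 / 4000))


class TestDatasetGeneration:
    def test_nc_sample_has_no_dual_stained_truth(self, tmp_path, content_layout):
        channels, amounts = content_layout
        spec = SceneSpec(image_shape=(256, 256), n_vesicles=15, fractions={"P1": 0.5, "P2": 0.5}, seed=0)
        truths = generate_dataset(tmp_path, {"NC": spec}, n_fields=2)
        assert (truths["NC"]["population"] != "PC").all()

    def test_m4_fraction_matches_ratio(self, tmp_path, content_layout):
        channels, amounts = content_layout
        f = mixture_fractions(MIXTURE_RATIOS["M4"])
        spec = SceneSpec(image_shape=(768, 768), n_vesicles=50, fractions=f, seed=1)
        truths = generate_dataset(tmp_path, {"M4": spec}, n_fields=2)
        realized = (truths["M4"]["population"] == "PC").mean()
        assert realized == pytest.approx(0.05 / 2.05, abs=0.01)  # exact up to rounding of 100

    def test_fixed_seed_gives_identical_ground_truth_files(self, tmp_path, content_layout):
        spec = SceneSpec(image_shape=(256, 256), n_vesicles=10, seed=9)
        generate_dataset(tmp_path / "a", {"S": spec}, n_fields=1)
        generate_dataset(tmp_path / "b", {"S": spec}, n_fields=1)
        assert (tmp_path / "a/S/ground_truth.csv").read_bytes() == (
            tmp_path / "b/S/ground_truth.csv"
        ).read_bytes()

    def test_emitted_layout_is_readable_by_io(self, tmp_path, content_layout):
        channels, _ = content_layout
        spec = SceneSpec(image_shape=(256, 256), n_vesicles=10, seed=3)
        generate_dataset(tmp_path, {"S": spec}, n_fields=3)
        fields = read_dataset(tmp_path / "S", channels, AcquisitionMeta(grid_rows=2, grid_cols=2))
        assert len(fields) == 3
        assert set(fields[0].channels) == {"rho", "dexA", "dexB"}
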