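import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from guvcolocal.io import AcquisitionMeta
from guvcolocal.population import (
    NotBimodalError,
    ThresholdSet,
    classify,
    compensate_radius,
    correct_false_positives,
    estimate_concentration,
    find_antimode,
    fit_sedimentation,
    optimize_correlation_threshold,
    projected_radius,
    sample_mixture,
)


class TestAntimode:
    def test_separated_mixture_threshold_in_gap(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(0, 0.5, 500), rng.normal(10, 0.5, 500)])
        res = find_antimode(values)
        assert 3.0 < res.threshold < 7.0

    def test_standard_mixture_near_midpoint(self):
        rng = np.random.default_rng(42)
        values = np.concatenate([rng.normal(0, 1, 1000), rng.normal(8, 1, 1000)])
        res = find_antimode(values)
        assert abs(res.threshold - 4.0) <= 0.75

    def test_unimodal_raises(self):
        rng = np.random.default_rng(1)
        with pytest.raises(NotBimodalError, match="not bimodal"):
            find_antimode(rng.normal(0, 1, 2000))

    def test_too_few_values_raises(self):
        with pytest.raises(NotBimodalError):
            find_antimode(np.arange(10))

    def test_log_scale_handles_disparate_mode_widths(self):
        """A razor-thin negative mode next to a broad lognormal positive mode
        (typical of fluorescence intensities) is thresholded in the gap."""
        rng = np.random.default_rng(9)
        neg = np.exp(rng.normal(np.log(0.05), 0.05, 500))
        pos = np.exp(rng.normal(np.log(1.0), 0.4, 500))
        values = np.concatenate([neg, pos])
        res = find_antimode(values, scale="log")
        assert 0.08 < res.threshold < 0.7


class TestSampleMixture:
    def test_zero_fraction_draws_only_negatives(self):
        values, labels = sample_mixture([0.0], [1.0], 0.0, 500, seed=0)
        assert not labels.any()
        assert (values == 0.0).all()

    def test_reproducible_for_fixed_seed(self):
        a, la = sample_mixture(np.arange(10.0), np.arange(10.0, 20.0), 0.4, 1000, seed=5)
        b, lb = sample_mixture(np.arange(10.0), np.arange(10.0, 20.0), 0.4, 1000, seed=5)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(la, lb)

    def test_positive_count_within_binomial_bound(self):
        values, labels = sample_mixture([0.0], [1.0], 0.3, 10_000, seed=3)
        assert abs(values.mean() - 0.3) <= 3 * np.sqrt(0.3 * 0.7 / 10_000)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            sample_mixture([], [1.0], 0.5, 10)


class TestThresholdOptimization:
    def test_separated_pools_give_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        neg = rng.uniform(0.0, 0.2, 400)
        pos = rng.uniform(0.8, 1.0, 400)
        ts, table = optimize_correlation_threshold(neg, pos, fractions=(0.2, 0.5), n=1000, seed=1)
        assert (table["accuracy"] == 1.0).all()
        assert 0.2 < ts.correlation_threshold < 0.8
        assert ts.provenance == "resampled_synthetic"

    def test_single_fraction_table_has_one_row(self):
        rng = np.random.default_rng(0)
        _, table = optimize_correlation_threshold(
            rng.normal(0, 0.05, 300), rng.normal(1, 0.05, 300), fractions=(0.5,), n=500, seed=0
        )
        assert len(table) == 1

    def test_overlapping_pools_near_bayes_accuracy(self):
        rng = np.random.default_rng(7)
        neg = rng.normal(0.1, 0.1, 5000)
        pos = rng.normal(0.7, 0.1, 5000)
        ts, table = optimize_correlation_threshold(neg, pos, fractions=(0.5,), n=4000, seed=2)
        # Bayes rate at equal priors: Phi(-3) mass on each side of 0.4
        from scipy.stats import norm

        bayes = 1.0 - norm.cdf((0.4 - 0.1) / 0.1)
        accuracy = table["accuracy"].iloc[0]
        assert accuracy == pytest.approx(1.0 - bayes, abs=0.03)


class TestClassification:
    def _records(self):
        return pd.DataFrame(
            {
                "object_id": [1, 2, 3, 4],
                "field_index": [0, 0, 0, 0],
                "lum_mean_a": [5.0, 0.1, 5.0, 0.1],
                "lum_mean_b": [5.0, 0.1, 0.1, 5.0],
                "mem_mean_a": [1.0] * 4,
                "mem_mean_b": [1.0] * 4,
            }
        )

    def test_population_labels(self):
        ts = ThresholdSet(channel_thresholds={"a": 1.0, "b": 1.0})
        out = classify(self._records(), ts, ("a", "b"), {"a": "content", "b": "content"})
        assert list(out["population"]) == ["DP", "neg", "P1", "P2"]

    def test_exchange_by_correlation(self):
        ts = ThresholdSet(channel_thresholds={"a": 1.0, "b": 1.0}, correlation_threshold=0.5)
        scores = pd.DataFrame(
            {"object_id": [1, 2, 3, 4], "field_index": 0, "value": [0.9, 0.1, 0.6, 0.2]}
        )
        out = classify(
            self._records(), ts, ("a", "b"), {"a": "content", "b": "content"}, scores=scores
        )
        assert list(out["exchange_positive"]) == [True, False, True, False]


class TestFalsePositiveCorrection:
    @pytest.mark.parametrize("dp,nc,expected", [(8.0, 1.0, 7.0), (0.5, 1.0, 0.0), (12.5, 0.0, 12.5)])
    def test_subtraction_with_floor(self, dp, nc, expected):
        assert correct_false_positives(dp, nc) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            correct_false_positives(120.0, 0.0)


class TestConcentration:
    def test_reference_arithmetic(self):
        meta = AcquisitionMeta(chamber_thickness_um=120.0, dilution_factor=10.0)
        c = estimate_concentration(500, 1.0, meta)
        assert c == pytest.approx(500 / 0.12 * 10, rel=1e-12)

    def test_zero_objects(self):
        assert estimate_concentration(0, 1.0, AcquisitionMeta()) == 0.0

    def test_thickness_scaling(self):
        thin = estimate_concentration(100, 1.0, AcquisitionMeta(chamber_thickness_um=60.0))
        thick = estimate_concentration(100, 1.0, AcquisitionMeta(chamber_thickness_um=120.0))
        assert thin == pytest.approx(2 * thick)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            estimate_concentration(10, 0.0, AcquisitionMeta())


class TestRadiusCompensation:
    def test_equatorial_cut(self):
        R, flag = compensate_radius(3.0, 3.0)
        assert R == pytest.approx(3.0)
        assert not flag

    def test_reference_case(self):
        R, _ = compensate_radius(4.0, 2.0)
        assert R == pytest.approx(5.0)
        assert projected_radius(5.0, 2.0) == pytest.approx(4.0)

    def test_tangency_limit_flagged(self):
        R, flag = compensate_radius(0.0, 2.0)
        assert R == pytest.approx(1.0)
        assert flag

    @given(st.floats(1.0, 20.0))
    def test_roundtrip_identity(self, R):
        h = 2.0
        if R < h / 2:
            return
        r = projected_radius(R, h)
        back, _ = compensate_radius(r, h)
        assert back == pytest.approx(R, abs=1e-9)

    def test_subequatorial_sphere_rejected_forward(self):
        with pytest.raises(ValueError):
            projected_radius(0.5, 2.0)


class TestSedimentationFit:
    def test_noiseless_curve_recovered(self):
        t = np.linspace(2, 120, 10)
        counts = 100.0 * (1 - np.exp(-t / 30.0))
        fit = fit_sedimentation({120.0: (t, counts)})
        row = fit.per_thickness.iloc[0]
        assert row["n_inf"] == pytest.approx(100.0, rel=1e-3)
        assert row["tau_min"] == pytest.approx(30.0, rel=1e-3)

    def test_proportional_asymptotes_give_unit_r_squared(self):
        series = {}
        for thickness in (60.0, 120.0, 288.0, 500.0):
            t = np.linspace(2, 200, 8)
            series[thickness] = (t, 0.8 * thickness * (1 - np.exp(-t / 25.0)))
        fit = fit_sedimentation(series)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.slope == pytest.approx(0.8, rel=1e-3)

    def test_zero_counts_flagged_unidentifiable(self):
        t = np.linspace(0, 100, 6)
        fit = fit_sedimentation({60.0: (t, np.zeros_like(t))})
        row = fit.per_thickness.iloc[0]
        assert row["n_inf"] == 0.0
        assert not row["converged"]
        assert np.isnan(row["tau_min"])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_sedimentation({60.0: (np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))})
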