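"""End-to-end validation experiments against the synthetic generator.

These routines wire the full pipeline — render, segment, measure,
background-correct, threshold, classify — against ground truth, and are
shared by the test suite and the reproduction script. Problem sizes are
chosen so each experiment runs in minutes on one core: mixture-recovery
samples hold ~1000 vesicles across eight 1024-pixel fields; the detection
benchmarks use single 512-pixel fields.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .colocalization import estimate_background, subtract_background_records
from .evaluation import DetectionMetrics, match_objects
from .io import ChannelSpec, FieldOfView, grid_position
from .population import ThresholdSet, classify, correct_false_positives, find_antimode
from .segmentation import LabelMap, SegmentationParams, segment_field
from .synthesis import (
    MIXTURE_RATIOS,
    SceneSpec,
    allocate_populations,
    default_content_exchange_layout,
    mixture_fractions,
    render_scene,
)

__all__ = [
    "render_sample",
    "process_sample",
    "fluorescence_thresholds",
    "mixture_recovery_experiment",
    "segmentation_benchmark",
    "clean_scene_spec",
    "degraded_scene_spec",
]


def clean_scene_spec(seed: int = 0, n_vesicles: int = 60, size: int = 512) -> SceneSpec:
    """High-SNR, well-separated vesicles — the easy regime."""
    return SceneSpec(
        image_shape=(size, size),
        n_vesicles=n_vesicles,
        fractions={"P1": 0.5, "P2": 0.5},
        min_gap_px=10.0,
        seed=seed,
    )


def degraded_scene_spec(seed: int = 0, n_vesicles: int = 60, size: int = 512) -> SceneSpec:
    """Heterogeneous preparation: patchy membranes, bright multilamellar-like
    objects, oil-inclusion hot spots and out-of-focus haze."""
    return SceneSpec(
        image_shape=(size, size),
        n_vesicles=n_vesicles,
        fractions={"P1": 0.5, "P2": 0.5},
        min_gap_px=10.0,
        patchy_fraction=0.3,
        multilamellar_fraction=0.1,
        inclusion_fraction=0.2,
        haze_amplitude=0.25,
        haze_n=30,
        seed=seed,
    )


def render_sample(
    spec: SceneSpec,
    n_fields: int,
    channel_specs: list[ChannelSpec] | None = None,
    population_amounts: dict[str, dict[str, float]] | None = None,
) -> tuple[list[FieldOfView], pd.DataFrame]:
    """Render a multi-field sample in memory with sample-level population counts."""
    if channel_specs is None or population_amounts is None:
        channel_specs, population_amounts = default_content_exchange_layout()
    rng = np.random.default_rng(spec.seed)
    total = spec.n_vesicles * n_fields
    populations = allocate_populations(total, spec.fractions, rng)
    grid_cols = int(np.ceil(np.sqrt(n_fields)))
    grid_rows = int(np.ceil(n_fields / grid_cols))
    fovs: list[FieldOfView] = []
    gt_parts: list[pd.DataFrame] = []
    for f_idx in range(n_fields):
        field_seed = int(np.random.SeedSequence([spec.seed, f_idx]).generate_state(1)[0] % (2**31))
        scene = render_scene(
            replace(spec, seed=field_seed),
            channel_specs,
            population_amounts,
            populations=populations[f_idx * spec.n_vesicles : (f_idx + 1) * spec.n_vesicles],
        )
        fovs.append(
            FieldOfView(
                field_index=f_idx,
                grid_position=grid_position(f_idx, grid_rows, grid_cols),
                channels=scene.channels,
                pixel_size=spec.pixel_size,
            )
        )
        gt = scene.truth.copy()
        gt.insert(0, "field_index", f_idx)
        gt_parts.append(gt)
    return fovs, pd.concat(gt_parts, ignore_index=True)


def process_sample(
    fields: list[FieldOfView],
    channel_specs: list[ChannelSpec],
    params: SegmentationParams,
) -> tuple[pd.DataFrame, dict[int, LabelMap], dict[int, LabelMap]]:
    """Segment and measure every field; concatenate the object tables."""
    records_parts = []
    lipid_maps: dict[int, LabelMap] = {}
    content_maps: dict[int, LabelMap] = {}
    for fov in fields:
        lipid_map, content_map, records, _ = segment_field(fov, channel_specs, params)
        lipid_maps[fov.field_index] = lipid_map
        content_maps[fov.field_index] = content_map
        records_parts.append(records)
    non_empty = [r for r in records_parts if len(r)]
    records = (
        pd.concat(non_empty, ignore_index=True) if non_empty else pd.DataFrame()
    )
    return records, lipid_maps, content_maps


def fluorescence_thresholds(
    records_corrected: pd.DataFrame,
    pair: tuple[str, str],
    channel_roles: dict[str, str],
    intensity_stat: str = "mean",
) -> ThresholdSet:
    """Mixed-sample antimode thresholds for each channel of a pair."""
    thresholds: dict[str, float] = {}
    bandwidth = None
    for ch in pair:
        prefix = "lum" if channel_roles.get(ch) == "content" else "mem"
        values = records_corrected[f"{prefix}_{intensity_stat}_{ch}"]
        values = values.fillna(records_corrected[f"mem_{intensity_stat}_{ch}"])
        res = find_antimode(values.to_numpy(), scale="log")
        thresholds[ch] = res.threshold
        bandwidth = res.bandwidth
    return ThresholdSet(channel_thresholds=thresholds, provenance="mixed_sample", bandwidth=bandwidth)


def mixture_recovery_experiment(
    seed: int = 0,
    n_fields: int = 8,
    n_per_field: int = 125,
    samples: tuple[str, ...] = ("NC", "M1", "M2", "M3", "M4"),
    params: SegmentationParams | None = None,
) -> pd.DataFrame:
    """Recover the dual-stained fraction of the M-series mixtures end to end.

    For every sample the double-positive percentage is computed with
    mixed-sample antimode thresholds on the two content channels, then
    corrected by the double-positive rate of the negative control. Returns
    one row per sample with the generative and recovered percentages.
    """
    params = params or SegmentationParams()
    channel_specs, population_amounts = default_content_exchange_layout()
    roles = {s.channel_id: s.role for s in channel_specs}
    pair = ("dexA", "dexB")
    ss = np.random.SeedSequence(seed)
    sample_seeds = {s: int(st.generate_state(1)[0] % (2**31)) for s, st in zip(samples, ss.spawn(len(samples)))}

    results: dict[str, dict] = {}
    for sample_id in samples:
        fractions = mixture_fractions(MIXTURE_RATIOS[sample_id])
        spec = SceneSpec(
            n_vesicles=n_per_field,
            fractions={p: f for p, f in fractions.items() if f > 0},
            min_gap_px=8.0,
            seed=sample_seeds[sample_id],
        )
        fields, truth = render_sample(spec, n_fields, channel_specs, population_amounts)
        records, _, _ = process_sample(fields, channel_specs, params)
        background = estimate_background(records, channel_specs)
        corrected = subtract_background_records(records, background)
        thresholds = fluorescence_thresholds(corrected, pair, roles)
        labels = classify(corrected, thresholds, pair, roles)
        dp_percent = 100.0 * (labels["population"] == "DP").mean()
        results[sample_id] = {
            "sample": sample_id,
            "n_true": len(truth),
            "n_detected": len(records),
            "true_dp_percent": 100.0 * (truth["population"] == "PC").mean(),
            "dp_percent": dp_percent,
        }
    nc_dp = results["NC"]["dp_percent"] if "NC" in results else 0.0
    for sample_id, row in results.items():
        row["fp_corrected_dp_percent"] = correct_false_positives(row["dp_percent"], nc_dp)
        row["abs_error_pp"] = abs(row["fp_corrected_dp_percent"] - row["true_dp_percent"])
    return pd.DataFrame(results.values())


def segmentation_benchmark(
    seed: int = 0,
    n_scenes: int = 3,
    degraded: bool = False,
    params: SegmentationParams | None = None,
) -> tuple[DetectionMetrics, pd.DataFrame]:
    """Detection recall/precision against ground truth over seeded scenes."""
    params = params or SegmentationParams()
    channel_specs, population_amounts = default_content_exchange_layout()
    make_spec = degraded_scene_spec if degraded else clean_scene_spec
    ss = np.random.SeedSequence([seed, int(degraded)])
    rows = []
    tp = fp = fn = 0
    for i, child in enumerate(ss.spawn(n_scenes)):
        scene_seed = int(child.generate_state(1)[0] % (2**31))
        spec = make_spec(seed=scene_seed)
        scene = render_scene(spec, channel_specs, population_amounts)
        fov = FieldOfView(i, (0, 0), scene.channels, spec.pixel_size)
        _, _, records, _ = segment_field(fov, channel_specs, params)
        _, metrics = match_objects(scene.truth, records, image_shape=spec.image_shape)
        tp += metrics.tp
        fp += metrics.fp
        fn += metrics.fn
        rows.append(
            {
                "scene": i,
                "recall": metrics.recall,
                "precision": metrics.precision,
                "f1": metrics.f1,
                "tp": metrics.tp,
                "fp": metrics.fp,
                "fn": metrics.fn,
            }
        )
    overall = DetectionMetrics.from_counts(tp, fp, fn, "centroid distance <= GT radius")
    return overall, pd.DataFrame(rows)
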