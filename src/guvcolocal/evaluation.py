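"""Detection scoring against ground truth and inspection montages.

Detections are matched to ground-truth vesicles greedily by nearest
centroid under a distance cap (by default each ground-truth object's own
radius, so the criterion scales with vesicle size). Ground-truth objects
touching the image border are excluded before matching, mirroring manual
counting practice. Recall = TP/(TP+FN), precision = TP/(TP+FP), F1 their
harmonic mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colocalization import crop_window
from .io import FieldOfView

__all__ = ["DetectionMetrics", "match_objects", "make_panel"]


@dataclass
class DetectionMetrics:
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f1: float
    criterion: str

    @classmethod
    def from_counts(cls, tp: int, fp: int, fn: int, criterion: str) -> "DetectionMetrics":
        recall = tp / (tp + fn) if (tp + fn) else 1.0
        precision = tp / (tp + fp) if (tp + fp) else 1.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        return cls(tp, fp, fn, recall, precision, f1, criterion)


def match_objects(
    gt_table: pd.DataFrame,
    detected_table: pd.DataFrame,
    max_centroid_dist: float | None = None,
    image_shape: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, DetectionMetrics]:
    """Greedy one-to-one nearest-centroid matching under a distance cap.

    ``gt_table`` needs columns center_row / center_col / radius_px (and is
    filtered of border objects when ``image_shape`` is given);
    ``detected_table`` needs centroid_row / centroid_col. When
    ``max_centroid_dist`` is None the cap is each ground-truth object's own
    radius. Returns the match table and the detection metrics.
    """
    gt = gt_table.reset_index(drop=True)
    if image_shape is not None and len(gt):
        h, w = image_shape
        inside = (
            (gt["center_row"] - gt["radius_px"] >= 0)
            & (gt["center_col"] - gt["radius_px"] >= 0)
            & (gt["center_row"] + gt["radius_px"] <= h - 1)
            & (gt["center_col"] + gt["radius_px"] <= w - 1)
        )
        gt = gt[inside].reset_index(drop=True)
    det = detected_table.reset_index(drop=True)
    n_gt, n_det = len(gt), len(det)
    criterion = (
        f"centroid distance <= {max_centroid_dist}"
        if max_centroid_dist is not None
        else "centroid distance <= GT radius"
    )
    if n_gt == 0 or n_det == 0:
        metrics = DetectionMetrics.from_counts(0, n_det, n_gt, criterion)
        return pd.DataFrame(columns=["gt_index", "det_index", "distance"]), metrics

    gc = gt[["center_row", "center_col"]].to_numpy()
    dc = det[["centroid_row", "centroid_col"]].to_numpy()
    dist = np.hypot(gc[:, None, 0] - dc[None, :, 0], gc[:, None, 1] - dc[None, :, 1])
    caps = (
        np.full(n_gt, max_centroid_dist)
        if max_centroid_dist is not None
        else gt["radius_px"].to_numpy()
    )
    candidates = np.argwhere(dist <= caps[:, None])
    order = np.argsort(dist[candidates[:, 0], candidates[:, 1]], kind="stable")
    gt_used = np.zeros(n_gt, dtype=bool)
    det_used = np.zeros(n_det, dtype=bool)
    matches = []
    for gi, di in candidates[order]:
        if gt_used[gi] or det_used[di]:
            continue
        gt_used[gi] = True
        det_used[di] = True
        matches.append({"gt_index": int(gi), "det_index": int(di), "distance": float(dist[gi, di])})
    tp = len(matches)
    metrics = DetectionMetrics.from_counts(tp, n_det - tp, n_gt - tp, criterion)
    return pd.DataFrame(matches, columns=["gt_index", "det_index", "distance"]), metrics


def make_panel(
    records: pd.DataFrame,
    fields: list[FieldOfView],
    channel_ids: list[str],
    n: int = 121,
    seed: int = 0,
    crop_px: int = 31,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Montage of sampled objects: merged crop with single-channel crops below.

    Defaults to 121 objects (an 11x11 grid of cells); when fewer are
    available all are shown with a warning. Each cell stacks the merged
    (channel-mean) crop on top of one crop per channel. Also returns the
    object-id manifest so false positives/negatives can be counted by hand.
    Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    if len(records) < n:
        warnings.warn(f"requested {n} objects but only {len(records)} available", stacklevel=2)
        chosen = records.reset_index(drop=True)
    else:
        idx = rng.choice(len(records), size=n, replace=False)
        chosen = records.reset_index(drop=True).iloc[np.sort(idx)].reset_index(drop=True)
    by_index = {f.field_index: f for f in fields}
    if crop_px % 2 == 0:
        crop_px += 1
    n_cells = len(chosen)
    grid_cols = int(np.ceil(np.sqrt(n_cells))) if n_cells else 1
    grid_rows = int(np.ceil(n_cells / grid_cols)) if n_cells else 1
    cell_h = crop_px * (1 + len(channel_ids))
    cell_w = crop_px
    panel = np.zeros((grid_rows * cell_h, grid_cols * cell_w), dtype=float)
    manifest = []
    for k, rec in enumerate(chosen.itertuples(index=False)):
        fov = by_index[rec.field_index]
        centroid = (rec.centroid_row, rec.centroid_col)
        crops = []
        for ch in channel_ids:
            win, _ = crop_window(fov.channels[ch], centroid, crop_px)
            win = np.asarray(win, dtype=float)
            peak = win.max()
            crops.append(win / peak if peak > 0 else win)
        merged = np.mean(crops, axis=0)
        stack = np.vstack([merged] + crops)
        gr, gc = divmod(k, grid_cols)
        panel[gr * cell_h : (gr + 1) * cell_h, gc * cell_w : (gc + 1) * cell_w] = stack
        manifest.append(
            {"cell": k, "object_id": rec.object_id, "field_index": rec.field_index}
        )
    return panel, pd.DataFrame(manifest, columns=["cell", "object_id", "field_index"])
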