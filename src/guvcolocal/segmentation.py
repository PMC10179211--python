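"""Vesicle segmentation from membrane- and content-marker channels.

Detection runs per channel role. All channels of a role are combined
(pixel-wise maximum after per-channel min-max normalization), then pushed
through a fixed chain: Gaussian smoothing, local contrast enhancement
(CLAHE), thresholding (global Otsu or local mean), morphological closing,
hole filling (membrane rings become filled disks), an optional
distance-transform watershed to split touching objects, and 8-connected
labelling. Objects are then filtered on area, convexity (solidity) and
border contact — the convexity filter is what suppresses spurious blobs on
empty, noise-only fields — and measured into per-vesicle records.

Content-marker objects are matched to membrane objects by pixel-overlap
plurality; unmatched content objects (lipid-negative debris) are excluded
from the vesicle table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import exposure, filters, measure, morphology, segmentation as sk_seg
from skimage.feature import peak_local_max

from .io import ChannelSpec, FieldOfView

__all__ = [
    "SegmentationParams",
    "LabelMap",
    "combine_role_channels",
    "segment_role",
    "filter_labels",
    "measure_objects",
    "segment_field",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the detection chain.

    ``max_foreground_fraction`` is a sanity guard: if thresholding marks more
    than this fraction of the field as foreground the field is treated as
    signal-free (a threshold computed on pure noise splits the noise in half
    and would otherwise flood the field with spurious objects).
    """

    smoothing_radius_px: float = 1.0
    clahe_tile_px: int = 64
    clahe_clip: float = 0.02
    threshold_method: str = "otsu"
    hysteresis_low_fraction: float = 0.7
    local_block_px: int = 51
    min_area_px: int = 20
    solidity_min: float = 0.8
    exclude_border: bool = True
    split_touching: bool = True
    max_foreground_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.local_block_px % 2 == 0:
            raise ValueError("local_block_px must be odd")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if not (0.0 <= self.solidity_min <= 1.0):
            raise ValueError("solidity_min must lie in [0, 1]")
        if self.threshold_method not in ("otsu", "local_mean"):
            raise ValueError("threshold_method must be 'otsu' or 'local_mean'")


@dataclass
class LabelMap:
    """Integer object-identity grid for one channel role of one field."""

    grid: np.ndarray
    role: str
    field_index: int

    @property
    def n_objects(self) -> int:
        return int(self.grid.max())


def _normalize(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    lo, hi = grid.min(), grid.max()
    if hi == lo:
        return np.zeros_like(grid)
    return (grid - lo) / (hi - lo)


def combine_role_channels(field: FieldOfView, role: str, channel_specs: list[ChannelSpec]) -> np.ndarray:
    """Pixel-wise maximum of a role's channels after min-max normalization.

    Normalization lets differently scaled markers contribute equally.
    """
    ids = [s.channel_id for s in channel_specs if s.role == role]
    grids = [field.channels[i] for i in ids if i in field.channels]
    if not grids:
        if role == "lipid":
            raise ValueError(f"field {field.field_index}: no lipid channel to segment")
        return np.zeros(field.shape, dtype=float)
    combined = _normalize(grids[0])
    for g in grids[1:]:
        combined = np.maximum(combined, _normalize(g))
    return combined


def segment_role(combined: np.ndarray, role: str, params: SegmentationParams, field_index: int = 0) -> LabelMap:
    """Run the detection chain on a combined role image normalized to [0, 1]."""
    img = np.asarray(combined, dtype=float)
    empty = LabelMap(np.zeros(img.shape, dtype=np.int32), role, field_index)
    if img.max() == img.min():
        return empty
    if params.smoothing_radius_px > 0:
        img = ndimage.gaussian_filter(img, params.smoothing_radius_px)
    img = _normalize(img)
    if params.clahe_tile_px > 0:
        img = exposure.equalize_adapthist(
            img, kernel_size=params.clahe_tile_px, clip_limit=params.clahe_clip
        )
    if params.threshold_method == "otsu":
        thr = filters.threshold_otsu(img)
        if params.hysteresis_low_fraction < 1.0:
            # dim stretches of unevenly stained (phase-separated) rings stay
            # connected to their bright segments at the lower threshold
            binary = filters.apply_hysteresis_threshold(
                img, thr * params.hysteresis_low_fraction, thr
            )
        else:
            binary = img > thr
    else:
        thr = filters.threshold_local(img, block_size=params.local_block_px, method="mean")
        binary = img > thr
    if binary.mean() > params.max_foreground_fraction:
        # threshold failed to isolate signal (e.g. noise-only field)
        return empty
    binary = ndimage.binary_closing(binary, structure=morphology.disk(1))
    if role == "lipid":
        binary = ndimage.binary_fill_holes(binary)
    if params.split_touching:
        labels = _split_touching(binary)
    else:
        labels, _ = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    return LabelMap(labels.astype(np.int32), role, field_index)


def _split_touching(binary: np.ndarray) -> np.ndarray:
    """Split components holding several convex bodies; leave single vesicles alone.

    Per component, candidate centers are distance-transform maxima separated
    by at least ~0.8x the inscribed radius and at least 30% as deep as the
    deepest one; a single surviving center keeps the component whole, two or
    more trigger a watershed. This resolves tangent or halo-bridged vesicle
    pairs without fragmenting large or unevenly stained single objects.
    """
    coarse, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    solidity = {p.label: p.solidity for p in measure.regionprops(coarse)}
    out = np.zeros(binary.shape, dtype=np.int32)
    next_label = 1
    for lab, sl in enumerate(ndimage.find_objects(coarse), start=1):
        if sl is None:
            continue
        comp = np.pad(coarse[sl] == lab, 1)
        dist = ndimage.distance_transform_edt(comp)
        rmax = dist.max()
        view = out[sl]
        inner = comp[1:-1, 1:-1]
        if rmax < 4.0 or solidity.get(lab, 0.0) < 0.6:
            # thin or strongly non-convex structures (unclosed ring arcs,
            # debris) are never split: beading them into convex pieces
            # would fabricate objects; merged vesicle pairs stay compact
            view[inner] = next_label
            next_label += 1
            continue
        min_dist = max(3, int(round(0.8 * rmax)))
        peaks = peak_local_max(
            dist,
            min_distance=min_dist,
            threshold_abs=max(2.0, 0.3 * rmax),
            exclude_border=False,
        )
        if len(peaks) < 2:
            view[inner] = next_label
            next_label += 1
            continue
        markers = np.zeros(comp.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        ws = sk_seg.watershed(-dist, markers, mask=comp, connectivity=2)[1:-1, 1:-1]
        for i in range(1, ws.max() + 1):
            piece = ws == i
            if piece.any():
                view[piece] = next_label
                next_label += 1
    return out


def filter_labels(labelmap: LabelMap, params: SegmentationParams) -> tuple[LabelMap, pd.DataFrame]:
    """Drop small, non-convex and border-touching objects; relabel consecutively.

    Returns the filtered map and a rejection log with one row per removed
    object (columns: label, reason).
    """
    grid = labelmap.grid
    h, w = grid.shape
    rejections: list[dict] = []
    keep = np.zeros(grid.max() + 1, dtype=bool)
    for prop in measure.regionprops(grid):
        reason = None
        if prop.area < params.min_area_px:
            reason = "area"
        elif prop.solidity < params.solidity_min:
            reason = "solidity"
        elif params.exclude_border:
            r0, c0, r1, c1 = prop.bbox
            if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
                reason = "border"
        if reason is None:
            keep[prop.label] = True
        else:
            rejections.append({"label": prop.label, "reason": reason})
    kept_labels = np.flatnonzero(keep)
    lut = np.zeros(grid.max() + 1, dtype=np.int32)
    lut[kept_labels] = np.arange(1, kept_labels.size + 1, dtype=np.int32)
    # identity-preserving relabel: touching objects from a watershed split
    # must not be merged back by a connected-component pass
    out = LabelMap(lut[grid], labelmap.role, labelmap.field_index)
    log = pd.DataFrame(rejections, columns=["label", "reason"])
    log.insert(0, "field_index", labelmap.field_index)
    log.insert(1, "role", labelmap.role)
    return out, log


def _match_content_to_lipid(lipid: np.ndarray, content: np.ndarray) -> dict[int, int]:
    """Map lipid label -> content label by pixel-overlap plurality."""
    sel = content > 0
    if not sel.any():
        return {}
    pairs = np.stack([content[sel], lipid[sel]])
    uniq, counts = np.unique(pairs, axis=1, return_counts=True)
    # best lipid label per content object
    best: dict[int, tuple[int, int]] = {}
    for (c_lab, l_lab), n in zip(uniq.T, counts):
        c_lab, l_lab, n = int(c_lab), int(l_lab), int(n)
        if c_lab == 0:
            continue
        if c_lab not in best or n > best[c_lab][1]:
            best[c_lab] = (l_lab, n)
    out: dict[int, int] = {}
    for c_lab, (l_lab, _) in best.items():
        if l_lab > 0 and l_lab not in out:
            out[l_lab] = c_lab
    return out


def measure_objects(
    lipid_map: LabelMap,
    content_map: LabelMap | None,
    field: FieldOfView,
    channel_specs: list[ChannelSpec],
) -> pd.DataFrame:
    """One record per membrane object: morphology plus per-channel statistics.

    Membrane statistics are computed over the object's lipid-map pixels and
    lumen statistics over its matched content-map pixels (NaN when no content
    object matches). ``obj_min_<ch>`` is the minimum over the union of both
    regions and feeds the background estimate.
    """
    grid = lipid_map.grid
    if content_map is not None and content_map.grid.shape != grid.shape:
        raise ValueError("lipid and content maps have mismatched shapes")
    for ch, g in field.channels.items():
        if g.shape != grid.shape:
            raise ValueError(f"channel {ch} shape {g.shape} != label map {grid.shape}")
    h, w = grid.shape
    content_grid = content_map.grid if content_map is not None else np.zeros_like(grid)
    matches = _match_content_to_lipid(grid, content_grid)
    rows: list[dict] = []
    for prop in measure.regionprops(grid):
        minor = prop.axis_minor_length
        major = prop.axis_major_length
        aspect = float(major / minor) if minor > 0 else np.nan
        r0, c0, r1, c1 = prop.bbox
        rec: dict = {
            "object_id": int(prop.label),
            "field_index": field.field_index,
            "centroid_row": float(prop.centroid[0]),
            "centroid_col": float(prop.centroid[1]),
            "area_px": int(prop.area),
            "equivalent_radius_um": float(field.pixel_size * np.sqrt(prop.area / np.pi)),
            "compensated_radius_um": np.nan,  # filled by the population step
            "aspect_ratio": aspect,
            "solidity": float(prop.solidity),
            "touches_border": bool(r0 == 0 or c0 == 0 or r1 == h or c1 == w),
            "content_label": int(matches.get(prop.label, 0)),
        }
        lip_pixels = grid == prop.label
        c_lab = matches.get(prop.label, 0)
        lum_pixels = (content_grid == c_lab) if c_lab > 0 else None
        rec["lum_area_px"] = int(lum_pixels.sum()) if lum_pixels is not None else 0
        for spec in channel_specs:
            if spec.channel_id not in field.channels:
                continue
            ch = spec.channel_id
            img = np.asarray(field.channels[ch], dtype=float)
            mem = img[lip_pixels]
            rec[f"mem_mean_{ch}"] = float(mem.mean())
            rec[f"mem_min_{ch}"] = float(mem.min())
            rec[f"mem_max_{ch}"] = float(mem.max())
            rec[f"mem_sum_{ch}"] = float(mem.sum())
            if lum_pixels is not None:
                lum = img[lum_pixels]
                rec[f"lum_mean_{ch}"] = float(lum.mean())
                rec[f"lum_min_{ch}"] = float(lum.min())
                rec[f"lum_max_{ch}"] = float(lum.max())
                rec[f"lum_sum_{ch}"] = float(lum.sum())
                rec[f"obj_min_{ch}"] = float(min(mem.min(), lum.min()))
            else:
                rec[f"lum_mean_{ch}"] = np.nan
                rec[f"lum_min_{ch}"] = np.nan
                rec[f"lum_max_{ch}"] = np.nan
                rec[f"lum_sum_{ch}"] = np.nan
                rec[f"obj_min_{ch}"] = float(mem.min())
        rows.append(rec)
    return pd.DataFrame(rows)


def segment_field(
    field: FieldOfView,
    channel_specs: list[ChannelSpec],
    params: SegmentationParams,
) -> tuple[LabelMap, LabelMap, pd.DataFrame, pd.DataFrame]:
    """Full per-field pipeline: segment both roles, filter, measure.

    Returns ``(lipid_map, content_map, records, rejection_log)``.
    """
    lipid_raw = segment_role(
        combine_role_channels(field, "lipid", channel_specs), "lipid", params, field.field_index
    )
    lipid_map, rej_l = filter_labels(lipid_raw, params)
    has_content = any(s.role == "content" and s.channel_id in field.channels for s in channel_specs)
    if has_content:
        content_raw = segment_role(
            combine_role_channels(field, "content", channel_specs), "content", params, field.field_index
        )
        content_map, rej_c = filter_labels(content_raw, params)
    else:
        content_map = LabelMap(np.zeros(field.shape, dtype=np.int32), "content", field.field_index)
        rej_c = pd.DataFrame(columns=["field_index", "role", "label", "reason"])
    records = measure_objects(lipid_map, content_map, field, channel_specs)
    log = pd.concat([rej_l, rej_c], ignore_index=True)
    return lipid_map, content_map, records, log
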