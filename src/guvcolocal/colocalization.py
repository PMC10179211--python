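"""Per-object colocalization scoring between fluorescence channel pairs.

A vesicle's score is computed on the pixel vectors of a square window
centered on its centroid, cropped identically from both channels of a pair.
The window may be restricted by a region mask (the object's membrane pixels,
its lumen pixels, or their union); without a mask the score also reflects
neighbouring vesicles inside the window, which is exactly the dependency the
masks are there to remove. Pixels padded in when a window clips the field
border are excluded from every score.

Supported metrics: Pearson product-moment correlation, Spearman and Kendall
(tau-b) rank correlations, and the Manders colocalization coefficient with
two threshold modes (window median, or the minimum intensity found inside
the object).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ChannelSpec, FieldOfView
from .segmentation import LabelMap

__all__ = [
    "ColocParams",
    "DegenerateScoreError",
    "estimate_background",
    "subtract_background",
    "subtract_background_records",
    "crop_window",
    "region_mask",
    "correlation",
    "manders",
    "score_objects",
    "default_window_width",
]

CORRELATION_METHODS = ("pearson", "spearman", "kendall", "manders")
MASK_MODES = ("none", "membrane", "lumen", "both")


class DegenerateScoreError(ValueError):
    """Raised when a score is undefined (constant input, empty mask, zero mass)."""


@dataclass(frozen=True)
class ColocParams:
    window_width_px: int = 31
    mask_mode: str = "none"
    method: str = "pearson"
    manders_threshold_mode: str = "window_median"

    def __post_init__(self) -> None:
        if self.window_width_px % 2 == 0 or self.window_width_px < 3:
            raise ValueError("window_width_px must be odd and >= 3")
        if self.mask_mode not in MASK_MODES:
            raise ValueError(f"mask_mode must be one of {MASK_MODES}")
        if self.method not in CORRELATION_METHODS:
            raise ValueError(f"method must be one of {CORRELATION_METHODS}")
        if self.manders_threshold_mode not in ("window_median", "object_min"):
            raise ValueError("manders_threshold_mode must be 'window_median' or 'object_min'")


def default_window_width(records: pd.DataFrame, pixel_size: float) -> int:
    """Adaptive window: 3x the dataset's median object diameter, rounded odd."""
    diam_px = 2.0 * np.sqrt(records["area_px"].median() / np.pi)
    width = int(round(3.0 * diam_px))
    if width % 2 == 0:
        width += 1
    return max(width, 3)


# ---------------------------------------------------------------------------
# background subtraction


def estimate_background(records: pd.DataFrame, channel_specs: list[ChannelSpec]) -> dict[str, float]:
    """Per-channel background: mean over objects of the object's minimum pixel.

    Every detected vesicle contributes the darkest pixel found inside it
    (membrane plus lumen); averaging these minima gives a robust estimate of
    the channel's diffuse background without needing cell-free regions.
    """
    background: dict[str, float] = {}
    for spec in channel_specs:
        col = f"obj_min_{spec.channel_id}"
        if col in records.columns and len(records) and records[col].notna().any():
            background[spec.channel_id] = float(records[col].mean())
        else:
            import warnings

            warnings.warn(f"no objects to estimate background for {spec.channel_id}; using 0", stacklevel=2)
            background[spec.channel_id] = 0.0
    return background


def subtract_background(fields: list[FieldOfView], background: dict[str, float]) -> list[FieldOfView]:
    """Return copies of the fields with per-channel background removed (clamped at 0)."""
    out = []
    for fov in fields:
        channels = {
            ch: np.clip(np.asarray(g, dtype=float) - background.get(ch, 0.0), 0.0, None)
            for ch, g in fov.channels.items()
        }
        out.append(FieldOfView(fov.field_index, fov.grid_position, channels, fov.pixel_size))
    return out


def subtract_background_records(records: pd.DataFrame, background: dict[str, float]) -> pd.DataFrame:
    """Background-correct the per-object intensity statistics (clamped at 0)."""
    out = records.copy()
    for ch, b in background.items():
        for stat in ("mem_mean", "mem_min", "mem_max", "lum_mean", "lum_min", "lum_max", "obj_min"):
            col = f"{stat}_{ch}"
            if col in out.columns:
                out[col] = np.clip(out[col] - b, 0.0, None)
        for stat, area_col in (("mem_sum", "area_px"), ("lum_sum", "lum_area_px")):
            col = f"{stat}_{ch}"
            if col in out.columns and area_col in out.columns:
                # integrated intensity shifts by background x region area
                out[col] = np.clip(out[col] - b * out[area_col], 0.0, None)
    return out


# ---------------------------------------------------------------------------
# windows and masks


def crop_window(grid: np.ndarray, centroid: tuple[float, float], window_width_px: int) -> tuple[np.ndarray, np.ndarray]:
    """Square window centered on the rounded centroid.

    Returns ``(window, valid)`` where ``valid`` flags in-bounds pixels;
    out-of-bounds positions are filled with 0 and marked invalid.
    """
    if window_width_px % 2 == 0:
        raise ValueError("window width must be odd")
    grid = np.asarray(grid)
    h, w = grid.shape
    cr, cc = int(round(centroid[0])), int(round(centroid[1]))
    if not (0 <= cr < h and 0 <= cc < w):
        raise ValueError(f"centroid {centroid} outside grid {grid.shape}")
    half = window_width_px // 2
    window = np.zeros((window_width_px, window_width_px), dtype=grid.dtype)
    valid = np.zeros((window_width_px, window_width_px), dtype=bool)
    r0, r1 = cr - half, cr + half + 1
    c0, c1 = cc - half, cc + half + 1
    sr0, sc0 = max(r0, 0), max(c0, 0)
    sr1, sc1 = min(r1, h), min(c1, w)
    window[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = grid[sr0:sr1, sc0:sc1]
    valid[sr0 - r0 : sr1 - r0, sc0 - c0 : sc1 - c0] = True
    return window, valid


def region_mask(
    label_window: np.ndarray,
    object_id: int,
    mask_mode: str,
    content_window: np.ndarray | None = None,
    content_id: int = 0,
) -> np.ndarray:
    """Boolean region-of-interest mask within a cropped window.

    ``membrane`` keeps the object's own lipid-label pixels, ``lumen`` its
    matched content-label pixels, ``both`` their union; ``none`` keeps the
    whole window.
    """
    if mask_mode not in MASK_MODES:
        raise ValueError(f"unknown mask_mode {mask_mode!r}")
    if mask_mode == "none":
        return np.ones(label_window.shape, dtype=bool)
    membrane = label_window == object_id
    if mask_mode == "membrane":
        return membrane
    lumen = (
        (content_window == content_id)
        if (content_window is not None and content_id > 0)
        else np.zeros(label_window.shape, dtype=bool)
    )
    if mask_mode == "lumen":
        return lumen
    return membrane | lumen


# ---------------------------------------------------------------------------
# metrics


def correlation(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> float:
    """Correlation between two pixel vectors.

    Pearson is the product-moment coefficient; Spearman applies it to
    mid-ranks; Kendall is tau-b with tie correction (matching R's cor.test
    conventions). Constant input makes Pearson/Spearman undefined and raises
    :class:`DegenerateScoreError`.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise DegenerateScoreError("need at least 3 pixels")
    if method in ("pearson", "spearman") and (np.ptp(x) == 0 or np.ptp(y) == 0):
        raise DegenerateScoreError("constant input")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    if method == "kendall":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise DegenerateScoreError("constant input")
        return float(stats.kendalltau(x, y, variant="b").statistic)
    raise ValueError(f"unknown method {method!r}")


def manders(
    x: np.ndarray,
    y: np.ndarray,
    threshold_mode: str = "window_median",
    object_pixels_y: np.ndarray | None = None,
    threshold: float | None = None,
) -> float:
    """Manders coefficient of channel *x* with respect to channel *y*.

    M = sum of x over pixels where y exceeds its threshold, divided by the
    total x. The threshold is the window median of y (``window_median``), the
    minimum of y over the object's own pixels (``object_min``), or an
    explicit ``threshold``. Because both markers stain equivalent structures
    only this single direction is reported; which channel plays x is fixed by
    the declared pair order.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    total = x.sum()
    if total <= 0:
        raise DegenerateScoreError("zero total intensity in x")
    if threshold is None:
        if threshold_mode == "window_median":
            threshold = float(np.median(y))
        elif threshold_mode == "object_min":
            if object_pixels_y is None or len(object_pixels_y) == 0:
                raise ValueError("object_min mode requires the object's y pixels")
            threshold = float(np.min(object_pixels_y))
        else:
            raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    return float(x[y > threshold].sum() / total)


# ---------------------------------------------------------------------------
# batch scoring


def score_objects(
    records: pd.DataFrame,
    fields: list[FieldOfView],
    lipid_maps: dict[int, LabelMap],
    content_maps: dict[int, LabelMap],
    pairs: list[tuple[str, str]],
    params: ColocParams,
    methods: list[str] | None = None,
) -> pd.DataFrame:
    """One score per object x channel pair x method.

    Degenerate objects (constant signal, empty mask) are flagged rather than
    aborting the batch; their value is NaN and ``degenerate`` is True.
    """
    methods = methods or [params.method]
    by_index = {f.field_index: f for f in fields}
    rows: list[dict] = []
    for rec in records.itertuples(index=False):
        fov = by_index[rec.field_index]
        centroid = (rec.centroid_row, rec.centroid_col)
        lip_win, _ = crop_window(lipid_maps[rec.field_index].grid, centroid, params.window_width_px)
        con_grid = content_maps[rec.field_index].grid if rec.field_index in content_maps else None
        con_win = (
            crop_window(con_grid, centroid, params.window_width_px)[0] if con_grid is not None else None
        )
        mask = region_mask(lip_win, rec.object_id, params.mask_mode, con_win, int(rec.content_label))
        for ch_a, ch_b in pairs:
            win_a, valid = crop_window(fov.channels[ch_a], centroid, params.window_width_px)
            win_b, _ = crop_window(fov.channels[ch_b], centroid, params.window_width_px)
            sel = mask & valid
            for method in methods:
                value, degenerate = np.nan, False
                try:
                    if sel.sum() < 3:
                        raise DegenerateScoreError("no pixels under mask")
                    x, y = win_a[sel], win_b[sel]
                    if method == "manders":
                        if params.manders_threshold_mode == "object_min":
                            obj_y = win_b[(lip_win == rec.object_id) & valid]
                            value = manders(x, y, "object_min", object_pixels_y=obj_y)
                        else:
                            value = manders(x, y, "window_median")
                    else:
                        value = correlation(x, y, method)
                except DegenerateScoreError:
                    degenerate = True
                rows.append(
                    {
                        "object_id": rec.object_id,
                        "field_index": rec.field_index,
                        "channel_a": ch_a,
                        "channel_b": ch_b,
                        "method": method,
                        "mask_mode": params.mask_mode,
                        "value": value,
                        "degenerate": degenerate,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "object_id",
            "field_index",
            "channel_a",
            "channel_b",
            "method",
            "mask_mode",
            "value",
            "degenerate",
        ],
    )
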