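"""Reading and writing of tiled micrograph datasets and pipeline artifacts.

A dataset is a directory of single-page TIFF files, one per field of view and
channel, named ``field{index:04d}_{channel_id}.tif``. Fields are indexed in
acquisition order; the tiling order (snake-by-rows for a motorized-stage
composite, or plain row-major) maps the linear field index onto a position in
the stage grid. Channels carry a *role*: ``lipid`` channels image the vesicle
membrane (rings), ``content`` channels image the encapsulated lumen marker
(filled disks). At least one lipid channel is required — membrane fluorescence
is the detection signal.

Object tables are plain CSV with full-precision floats; label maps are
single-page unsigned-integer TIFFs. All round-trips are lossless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ChannelSpec",
    "AcquisitionMeta",
    "FieldOfView",
    "grid_position",
    "field_index_of",
    "read_dataset",
    "write_dataset",
    "write_objects",
    "read_objects",
    "write_label_map",
    "read_label_map",
    "load_channel_config",
    "save_channel_config",
]

FIELD_FILE_PATTERN = "field{index:04d}_{channel_id}.tif"

VALID_ROLES = ("lipid", "content")
VALID_TILE_ORDERS = ("snake_by_rows", "row_major")


@dataclass(frozen=True)
class ChannelSpec:
    """One fluorescence channel and its role in the assay.

    Parameters
    ----------
    channel_id : str
        Short unique identifier, also used in file names.
    role : {'lipid', 'content'}
        Whether the marker resides in the membrane or the lumen.
    marker_name : str
        Free-text fluorophore description (e.g. ``"DPPE-Rh"``).
    pair_group : str, optional
        Name of the exchange assay this channel belongs to; colocalization
        is only scored between channels sharing a pair group.
    """

    channel_id: str
    role: str
    marker_name: str = ""
    pair_group: str | None = None

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(f"role must be one of {VALID_ROLES}, got {self.role!r}")
        if not self.channel_id:
            raise ValueError("channel_id must be a non-empty string")


def validate_channel_specs(specs: Sequence[ChannelSpec]) -> None:
    """Check uniqueness of ids and that a membrane channel exists."""
    ids = [s.channel_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate channel ids in {ids}")
    if not any(s.role == "lipid" for s in specs):
        raise ValueError("at least one channel must have role 'lipid'")


@dataclass(frozen=True)
class AcquisitionMeta:
    """Stage-tiling layout and chamber geometry of an acquisition.

    ``plane_offset_um`` is the distance between the imaging plane and the
    coverslip the vesicles sediment onto (2 µm in the reference setup); it
    drives the spherical-cap radius compensation. ``chamber_thickness_um``
    and ``dilution_factor`` enter the concentration estimate.
    """

    grid_rows: int = 1
    grid_cols: int = 1
    tile_order: str = "snake_by_rows"
    overlap_fraction: float = 0.0
    plane_offset_um: float = 2.0
    chamber_thickness_um: float = 120.0
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.tile_order not in VALID_TILE_ORDERS:
            raise ValueError(f"tile_order must be one of {VALID_TILE_ORDERS}")
        if not (0.0 <= self.overlap_fraction < 0.5):
            raise ValueError("overlap_fraction must lie in [0, 0.5)")
        if self.plane_offset_um <= 0:
            raise ValueError("plane_offset_um must be > 0")
        if self.chamber_thickness_um <= 0:
            raise ValueError("chamber_thickness_um must be > 0")
        if self.plane_offset_um > self.chamber_thickness_um:
            raise ValueError("plane_offset_um cannot exceed chamber_thickness_um")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")


@dataclass
class FieldOfView:
    """One tile: co-registered channel grids plus its grid position."""

    field_index: int
    grid_position: tuple[int, int]
    channels: dict[str, np.ndarray] = dc_field(default_factory=dict)
    pixel_size: float = 1.0  # µm per pixel

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape

    def validate(self) -> None:
        shapes = {ch: g.shape for ch, g in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"field {self.field_index}: inconsistent channel shapes {shapes}")


# ---------------------------------------------------------------------------
# tile-order arithmetic


def grid_position(field_index: int, rows: int, cols: int, tile_order: str = "snake_by_rows") -> tuple[int, int]:
    """Decode a linear acquisition index into a (row, col) stage position.

    Snake-by-rows reverses the column direction on every odd row, matching a
    motorized stage that rasters back and forth.
    """
    if not (0 <= field_index < rows * cols):
        raise ValueError(f"field_index {field_index} outside {rows}x{cols} grid")
    row, rem = divmod(field_index, cols)
    if tile_order == "snake_by_rows" and row % 2 == 1:
        col = cols - 1 - rem
    elif tile_order in VALID_TILE_ORDERS:
        col = rem
    else:
        raise ValueError(f"unknown tile_order {tile_order!r}")
    return row, col


def field_index_of(row: int, col: int, rows: int, cols: int, tile_order: str = "snake_by_rows") -> int:
    """Inverse of :func:`grid_position`."""
    if not (0 <= row < rows and 0 <= col < cols):
        raise ValueError(f"position ({row}, {col}) outside {rows}x{cols} grid")
    if tile_order == "snake_by_rows" and row % 2 == 1:
        rem = cols - 1 - col
    else:
        rem = col
    return row * cols + rem


def _crop_overlap(grid: np.ndarray, row: int, col: int, rows: int, cols: int, overlap: float) -> np.ndarray:
    """Crop a tile to its unique region: half the overlap from each shared edge."""
    if overlap == 0:
        return grid
    h, w = grid.shape
    dr = int(round(h * overlap / 2))
    dc = int(round(w * overlap / 2))
    top = dr if row > 0 else 0
    bottom = h - dr if row < rows - 1 else h
    left = dc if col > 0 else 0
    right = w - dc if col < cols - 1 else w
    return grid[top:bottom, left:right]


# ---------------------------------------------------------------------------
# dataset reading/writing


def read_dataset(
    root_path: str | Path,
    channel_specs: Sequence[ChannelSpec],
    meta: AcquisitionMeta,
    pixel_size: float = 1.0,
) -> list[FieldOfView]:
    """Read all fields of a tiled dataset in acquisition order.

    Expects one single-page TIFF per field and channel, named per
    ``FIELD_FILE_PATTERN``. Accepts 8/16-bit unsigned and float grids without
    rescaling. Missing channel files and inconsistent dimensions are hard
    errors naming the offending field.
    """
    root = Path(root_path)
    validate_channel_specs(channel_specs)
    n_fields = meta.grid_rows * meta.grid_cols
    # only read indices that exist on disk, but require channel completeness
    present = sorted(
        {int(p.name[5:9]) for p in root.glob("field????_*.tif")}
    )
    if not present:
        raise FileNotFoundError(f"no field TIFFs found under {root}")
    if present[-1] >= n_fields:
        raise ValueError(
            f"field index {present[-1]} exceeds declared {meta.grid_rows}x{meta.grid_cols} grid"
        )
    fields: list[FieldOfView] = []
    for idx in present:
        channels: dict[str, np.ndarray] = {}
        for spec in channel_specs:
            path = root / FIELD_FILE_PATTERN.format(index=idx, channel_id=spec.channel_id)
            if not path.exists():
                raise FileNotFoundError(
                    f"field {idx}: missing channel {spec.channel_id!r} ({path.name})"
                )
            channels[spec.channel_id] = np.asarray(tifffile.imread(path))
        row, col = grid_position(idx, meta.grid_rows, meta.grid_cols, meta.tile_order)
        if meta.overlap_fraction > 0:
            channels = {
                ch: _crop_overlap(g, row, col, meta.grid_rows, meta.grid_cols, meta.overlap_fraction)
                for ch, g in channels.items()
            }
        fov = FieldOfView(field_index=idx, grid_position=(row, col), channels=channels, pixel_size=pixel_size)
        fov.validate()
        fields.append(fov)
    return fields


def write_dataset(root_path: str | Path, fields: Iterable[FieldOfView]) -> None:
    """Write fields back out in the per-field, per-channel TIFF layout."""
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    for fov in fields:
        for ch, grid in fov.channels.items():
            path = root / FIELD_FILE_PATTERN.format(index=fov.field_index, channel_id=ch)
            tifffile.imwrite(path, np.asarray(grid))


# ---------------------------------------------------------------------------
# object tables

_BOOL_STRINGS = {"True", "False"}


def write_objects(records: pd.DataFrame, path: str | Path) -> None:
    """Write an object table as CSV; floats keep full round-trip precision."""
    records.to_csv(path, index=False)


def read_objects(path: str | Path) -> pd.DataFrame:
    """Read an object table written by :func:`write_objects`.

    Boolean columns are restored from their string serialization; all other
    dtypes follow pandas inference (exact for the numeric columns the
    pipeline writes).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    for col in df.columns:
        if df[col].dtype == object:
            values = set(df[col].dropna().unique())
            if values and values <= _BOOL_STRINGS:
                df[col] = df[col].map({"True": True, "False": False})
    return df


# ---------------------------------------------------------------------------
# label maps


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label image as a lossless single-page TIFF.

    Uses 16-bit unless a label exceeds 65535, in which case the dtype is
    promoted to 32-bit with a warning.
    """
    labels = np.asarray(labels)
    if labels.min() < 0:
        raise ValueError("label maps must be non-negative")
    if labels.max() > np.iinfo(np.uint16).max:
        warnings.warn("label map exceeds 16-bit capacity; writing 32-bit", stacklevel=2)
        out = labels.astype(np.uint32)
    else:
        out = labels.astype(np.uint16)
    tifffile.imwrite(path, out)


def read_label_map(path: str | Path) -> np.ndarray:
    arr = np.asarray(tifffile.imread(path))
    return arr.astype(np.int64)


# ---------------------------------------------------------------------------
# structured config


def save_channel_config(path: str | Path, specs: Sequence[ChannelSpec], meta: AcquisitionMeta) -> None:
    payload = {
        "channels": [
            {
                "channel_id": s.channel_id,
                "role": s.role,
                "marker_name": s.marker_name,
                "pair_group": s.pair_group,
            }
            for s in specs
        ],
        "acquisition": {
            "grid_rows": meta.grid_rows,
            "grid_cols": meta.grid_cols,
            "tile_order": meta.tile_order,
            "overlap_fraction": meta.overlap_fraction,
            "plane_offset_um": meta.plane_offset_um,
            "chamber_thickness_um": meta.chamber_thickness_um,
            "dilution_factor": meta.dilution_factor,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_channel_config(path: str | Path) -> tuple[list[ChannelSpec], AcquisitionMeta]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    specs = [ChannelSpec(**entry) for entry in payload["channels"]]
    validate_channel_specs(specs)
    meta = AcquisitionMeta(**payload.get("acquisition", {}))
    return specs, meta
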