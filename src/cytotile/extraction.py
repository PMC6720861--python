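"""Export: single-cell tables (CSV/FCS), channel-subset hyperstacks, montages.

Montages place tiles row-major at their physical grid positions; where tiles
overlap, the trailing overlap strip of the earlier tile is overwritten by
the later one (deterministic trim, no blending).  Hyperstack extraction can
mix raw channels with derived object channels (cell/nucleus label and
boundary images) in any requested order.  Cell tables round-trip through
CSV exactly and through FCS at float32 precision; the two formats share one
column naming convention, with ``ci:<channel>`` for whole-cell and
``ni:<channel>`` for nucleus-only mean intensities.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import fcs
from .config import ExperimentConfig, tile_physical_position
from .quantification import CellRecord
from .segmentation import LabelImage
from .tile_io import TileVolume, write_hyperstack

#: Derived object-image channel names understood by hyperstack extraction.
OBJECT_CHANNELS = (
    "cyto_cell_boundaries",
    "cyto_nucleus_boundaries",
    "cyto_cell_mask",
    "cyto_nucleus_mask",
)


class StitchError(RuntimeError):
    """A tile required for stitching is missing."""


class ChannelNameError(KeyError):
    """A requested channel name resolves to nothing."""


class SchemaError(ValueError):
    """Cell records disagree on their channel sets."""


@dataclass(frozen=True)
class MontageSpec:
    """What to stitch: channels, z-plane choice, optional crop and downscale."""

    region: int = 0
    channel_names: tuple[str, ...] = ()
    z_selection: int | str = "best"
    crop: tuple[int, int, int, int] | None = None  # (y0, x0, height, width)
    scale: int = 1

    def __post_init__(self) -> None:
        if self.scale < 1:
            raise ValueError("scale must be >= 1")


def montage_shape(config: ExperimentConfig) -> tuple[int, int]:
    """Stitched size of a full region grid under trailing-edge overlap trim."""
    return (
        config.grid_rows * (config.tile_height - config.overlap_y) + config.overlap_y,
        config.grid_cols * (config.tile_width - config.overlap_x) + config.overlap_x,
    )


def stitch_montage(
    tiles: Mapping[tuple[int, int], np.ndarray],
    config: ExperimentConfig,
    spec: MontageSpec | None = None,
) -> np.ndarray:
    """Stitch per-tile 2-D planes into one region image.

    ``tiles`` maps (row, col) to a (tile_height, tile_width) plane; every
    grid position must be present.  Tiles are pasted in row-major order at
    :func:`tile_physical_position`, so a later tile's leading edge replaces
    the earlier tile's trailing overlap strip.
    """
    if spec is None:
        spec = MontageSpec()
    out_shape = montage_shape(config)
    out: np.ndarray | None = None
    for row in range(config.grid_rows):
        for col in range(config.grid_cols):
            if (row, col) not in tiles:
                raise StitchError(f"missing tile at (row, col)=({row}, {col})")
            plane = np.asarray(tiles[(row, col)])
            if plane.shape != (config.tile_height, config.tile_width):
                raise StitchError(
                    f"tile ({row}, {col}) has shape {plane.shape}, expected "
                    f"({config.tile_height}, {config.tile_width})"
                )
            if out is None:
                out = np.zeros(out_shape, dtype=plane.dtype)
            y, x = tile_physical_position(config, spec.region, row, col)
            out[y:y + config.tile_height, x:x + config.tile_width] = plane
    assert out is not None
    if spec.crop is not None:
        y0, x0, h, w = spec.crop
        if y0 < 0 or x0 < 0 or y0 + h > out.shape[0] or x0 + w > out.shape[1]:
            raise ValueError(f"crop {spec.crop} outside montage bounds {out.shape}")
        out = out[y0:y0 + h, x0:x0 + w]
    if spec.scale > 1:
        out = out[::spec.scale, ::spec.scale]
    return out


# ---------------------------------------------------------------------------
# object images

def label_boundaries(labels: np.ndarray, high: int = 65535) -> np.ndarray:
    """Binary boundary image: label pixels 4-adjacent to another label or 0."""
    lab = np.asarray(labels)
    boundary = np.zeros(lab.shape, dtype=bool)
    boundary[:-1, :] |= (lab[:-1, :] != lab[1:, :]) & (lab[:-1, :] > 0)
    boundary[1:, :] |= (lab[1:, :] != lab[:-1, :]) & (lab[1:, :] > 0)
    boundary[:, :-1] |= (lab[:, :-1] != lab[:, 1:]) & (lab[:, :-1] > 0)
    boundary[:, 1:] |= (lab[:, 1:] != lab[:, :-1]) & (lab[:, 1:] > 0)
    return np.where(boundary, high, 0).astype(np.uint16)


def resolve_channel_plane(
    name: str,
    volume: TileVolume,
    config: ExperimentConfig,
    z: int,
    cells: LabelImage | None = None,
    nuclei: LabelImage | None = None,
) -> np.ndarray:
    """Fetch one named channel plane: raw/processed, or a derived object image."""
    if name in OBJECT_CHANNELS:
        source = cells if "cell" in name else nuclei
        if source is None:
            raise ChannelNameError(
                f"object channel {name!r} requested but no label image supplied"
            )
        if name.endswith("boundaries"):
            return label_boundaries(source.labels)
        return source.labels.astype(np.uint16)
    try:
        ch = config.find_channel(name)
    except KeyError:
        available = list(config.channel_names) + list(OBJECT_CHANNELS)
        raise ChannelNameError(
            f"unknown channel {name!r}; available: {available}"
        ) from None
    return volume.data[ch.cycle_index, z, ch.channel_index_in_cycle]


def extract_hyperstack(
    volume: TileVolume,
    config: ExperimentConfig,
    channel_names: Sequence[str],
    z_selection: int | Sequence[int] | str,
    out: str | os.PathLike,
    cells: LabelImage | None = None,
    nuclei: LabelImage | None = None,
) -> np.ndarray:
    """Write a hyperstack with exactly the requested channels, in order.

    ``z_selection`` is a plane index, a list of indices, or ``"all"``.
    Object channels (2-D) are replicated across the selected z-planes.
    Returns the (1, Z, C, Y, X) array that was written.
    """
    n_z = volume.data.shape[1]
    if z_selection == "all":
        z_list = list(range(n_z))
    elif isinstance(z_selection, (int, np.integer)):
        z_list = [int(z_selection)]
    else:
        z_list = [int(z) for z in z_selection]
    for z in z_list:
        if not 0 <= z < n_z:
            raise IndexError(f"z={z} out of range [0, {n_z})")

    planes = np.stack([
        np.stack([
            resolve_channel_plane(name, volume, config, z, cells, nuclei)
            for name in channel_names
        ])
        for z in z_list
    ])  # (Z, C, Y, X)
    stack = planes[np.newaxis]  # (1, Z, C, Y, X)
    write_hyperstack(stack, out, channel_names=list(channel_names))
    return stack


# ---------------------------------------------------------------------------
# cell tables

_SCALAR_COLUMNS = (
    "cell_id", "region", "tile", "centroid_y", "centroid_x",
    "global_y", "global_x", "best_z", "size", "diameter", "circularity",
    "nucleus_size", "neighbor_count", "contact_boundary",
)


def records_to_dataframe(records: Sequence[CellRecord]) -> pd.DataFrame:
    """Tabular form of cell records.

    Columns: the scalar fields, then ``ci:<channel>`` (cell mean) and
    ``ni:<channel>`` (nucleus mean) per channel, then ``neighbor_ids`` as a
    pipe-joined id list.
    """
    if not records:
        return pd.DataFrame(columns=list(_SCALAR_COLUMNS) + ["neighbor_ids"])
    channels = list(records[0].cell_means)
    for r in records:
        if list(r.cell_means) != channels or list(r.nucleus_means) != channels:
            raise SchemaError(
                f"cell {r.cell_id}: channel set differs from first record"
            )
    rows = []
    for r in records:
        row: dict = {c: getattr(r, c) for c in _SCALAR_COLUMNS}
        for ch in channels:
            row[f"ci:{ch}"] = r.cell_means[ch]
            row[f"ni:{ch}"] = r.nucleus_means[ch]
        row["neighbor_ids"] = "|".join(str(i) for i in r.neighbor_ids)
        rows.append(row)
    return pd.DataFrame(rows)


def export_cell_data(
    records: Sequence[CellRecord],
    format: str,
    out: str | os.PathLike,
) -> None:
    """Write cell records as CSV or FCS 3.1.

    CSV keeps every column including the ``neighbor_ids`` list; FCS keeps
    the numeric columns only (one parameter per column, one event per cell).
    """
    df = records_to_dataframe(records)
    if format == "csv":
        # %.17g round-trips float64 exactly
        df.to_csv(out, index=False, float_format="%.17g")
    elif format == "fcs":
        numeric = df.drop(columns=["neighbor_ids"])
        fcs.write_fcs(out, list(numeric.columns),
                      numeric.to_numpy(dtype=np.float32)
                      if len(numeric) else np.zeros((0, numeric.shape[1]),
                                                    dtype=np.float32))
    else:
        raise ValueError(f"unknown export format {format!r}; use 'csv' or 'fcs'")


def read_cell_data(path: str | os.PathLike, format: str | None = None) -> pd.DataFrame:
    """Read back an exported cell table (CSV or FCS) as a DataFrame."""
    if format is None:
        format = "fcs" if str(path).lower().endswith(".fcs") else "csv"
    if format == "csv":
        return pd.read_csv(path, keep_default_na=False,
                           dtype={"neighbor_ids": str},
                           float_precision="round_trip")
    names, data = fcs.read_fcs(path)
    return pd.DataFrame(data, columns=names)
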