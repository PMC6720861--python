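"""Experiment configuration: the single source of truth for a run.

A multiplexed acquisition is seven-dimensional: regions hold grids of tiles,
each tile is a z-stack captured over several imaging cycles, and each cycle
contributes a handful of channels.  Every cycle must contain exactly one
*reference* channel (normally a nuclear stain) so that cycles can be aligned
to each other; the remaining channels carry expression markers or a membrane
stain.  All pipeline behaviour — geometry, optics, which operations run and
with which parameters — is declared in one hierarchical YAML document so a
run can be reproduced from the configuration alone.

Variants of an experiment are expressed as *deltas*: small maps from dotted
key paths to replacement values applied on top of a template configuration.
"""

from __future__ import annotations

import copy
import io
import os
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

#: Smallest permitted tile edge, in pixels.  This is policy, not physics:
#: smaller fields of view are rejected unless ``allow_small_tiles`` is set.
MIN_TILE_EDGE = 88

SCHEMA_VERSION = 1

CHANNEL_ROLES = ("reference", "expression", "membrane")

#: Default raw file name template (see :mod:`cytotile.tile_io`).
DEFAULT_FILENAME_TEMPLATE = "R{region}_T{tile:03d}_C{cycle:02d}_Z{z:02d}_CH{channel}.tif"


class ConfigError(ValueError):
    """Base class for configuration validation failures."""


class MissingKeyError(ConfigError):
    """A required configuration key is absent."""


class SizeError(ConfigError):
    """Tile geometry violates the minimum-size policy or overlap bounds."""


class ChannelRoleError(ConfigError):
    """The channel table violates role constraints (e.g. no reference stain)."""


class DeltaError(ConfigError):
    """A delta path does not resolve and may not create new keys there."""


@dataclass(frozen=True)
class ChannelSpec:
    """One acquired channel: its position in the cycle structure and optics."""

    cycle_index: int
    channel_index_in_cycle: int
    name: str
    role: str
    emission_wavelength_nm: float

    def __post_init__(self) -> None:
        if self.role not in CHANNEL_ROLES:
            raise ChannelRoleError(
                f"channel {self.name!r}: role {self.role!r} not in {CHANNEL_ROLES}"
            )
        if not self.emission_wavelength_nm > 0:
            raise ConfigError(
                f"channel {self.name!r}: emission wavelength must be > 0"
            )


def _default_op_params() -> dict:
    return {
        "registration": {"enabled": True, "upsample_factor": 1},
        "deconvolution": {"enabled": False, "iterations": 10, "psf_size_xy": 17},
        "quality": {"enabled": True, "scorer": "log_variance"},
        "segmentation": {
            "enabled": True,
            "min_nucleus_size": 40,
            "smoothing_sigma": 2.0,
            "cell_mode": "radius",
            "radius": 5.0,
            "lambda": 1.0,
            "membrane_channel": None,
            "exclude_border_cells": False,
        },
        "quantification": {"enabled": True},
    }


@dataclass
class ExperimentConfig:
    """Validated description of one experiment.

    Counts are 1-based sizes; all indices used against this object (regions,
    tiles, cycles, z, channels) are 0-based regardless of the index base used
    in raw file names.
    """

    n_regions: int
    grid_rows: int
    grid_cols: int
    n_cycles: int
    n_z: int
    channels_per_cycle: int
    tile_height: int
    tile_width: int
    overlap_y: int = 0
    overlap_x: int = 0
    axial_step_um: float = 0.5
    lateral_pixel_size_um: float = 0.325
    objective_na: float = 0.75
    magnification: float = 20.0
    immersion_ri: float = 1.0
    sample_ri: float = 1.33
    channels: tuple[ChannelSpec, ...] = ()
    op_params: dict = field(default_factory=_default_op_params)
    commands: dict = field(default_factory=dict)
    filename_template: str = DEFAULT_FILENAME_TEMPLATE
    index_base: int = 1
    allow_small_tiles: bool = False
    schema_version: int = SCHEMA_VERSION

    # -- validation ---------------------------------------------------------

    def validate(self) -> "ExperimentConfig":
        counts = {
            "n_regions": self.n_regions,
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "n_cycles": self.n_cycles,
            "n_z": self.n_z,
            "channels_per_cycle": self.channels_per_cycle,
        }
        for key, value in counts.items():
            if not isinstance(value, int) or value < 1:
                raise ConfigError(f"{key} must be an integer >= 1, got {value!r}")
        if not self.allow_small_tiles:
            for key, value in (("tile_height", self.tile_height),
                               ("tile_width", self.tile_width)):
                if value < MIN_TILE_EDGE:
                    raise SizeError(
                        f"{key}={value} is below the minimum tile edge of "
                        f"{MIN_TILE_EDGE} pixels"
                    )
        if not (0 <= self.overlap_y < self.tile_height):
            raise SizeError(
                f"overlap_y={self.overlap_y} must satisfy 0 <= overlap_y < tile_height"
            )
        if not (0 <= self.overlap_x < self.tile_width):
            raise SizeError(
                f"overlap_x={self.overlap_x} must satisfy 0 <= overlap_x < tile_width"
            )
        if self.index_base not in (0, 1):
            raise ConfigError(f"index_base must be 0 or 1, got {self.index_base}")

        expected = self.n_cycles * self.channels_per_cycle
        if len(self.channels) != expected:
            raise ChannelRoleError(
                f"channel table has {len(self.channels)} entries; expected "
                f"{self.n_cycles} cycles x {self.channels_per_cycle} = {expected}"
            )
        names = [ch.name for ch in self.channels]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ChannelRoleError(f"channel names not unique: {dupes}")
        positions = {(ch.cycle_index, ch.channel_index_in_cycle) for ch in self.channels}
        if len(positions) != len(self.channels):
            raise ChannelRoleError("(cycle, channel) positions not unique")
        for cycle in range(self.n_cycles):
            refs = [ch for ch in self.channels
                    if ch.cycle_index == cycle and ch.role == "reference"]
            if len(refs) != 1:
                raise ChannelRoleError(
                    f"cycle {cycle} has {len(refs)} reference channels; "
                    "exactly one is required"
                )
        if not (0 < self.objective_na < max(self.immersion_ri, self.sample_ri)):
            raise ConfigError(
                f"objective NA {self.objective_na} must lie in (0, "
                f"max(immersion_ri, sample_ri)={max(self.immersion_ri, self.sample_ri)})"
            )
        return self

    # -- derived accessors --------------------------------------------------

    @property
    def n_tiles(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def channel_names(self) -> list[str]:
        return [ch.name for ch in self.channels]

    def channel(self, cycle: int, index_in_cycle: int) -> ChannelSpec:
        for ch in self.channels:
            if ch.cycle_index == cycle and ch.channel_index_in_cycle == index_in_cycle:
                return ch
        raise KeyError((cycle, index_in_cycle))

    def find_channel(self, name: str) -> ChannelSpec:
        for ch in self.channels:
            if ch.name == name:
                return ch
        raise KeyError(
            f"unknown channel {name!r}; available: {self.channel_names}"
        )

    def reference_channel(self, cycle: int) -> ChannelSpec:
        for ch in self.channels:
            if ch.cycle_index == cycle and ch.role == "reference":
                return ch
        raise ChannelRoleError(f"cycle {cycle} has no reference channel")

    def tile_row_col(self, tile: int) -> tuple[int, int]:
        """Row-major (row, col) grid coordinates of a linear tile index."""
        if not 0 <= tile < self.n_tiles:
            raise IndexError(f"tile {tile} out of range [0, {self.n_tiles})")
        return divmod(tile, self.grid_cols)

    def tile_index(self, row: int, col: int) -> int:
        if not (0 <= row < self.grid_rows and 0 <= col < self.grid_cols):
            raise IndexError(f"(row, col)=({row}, {col}) outside "
                             f"{self.grid_rows}x{self.grid_cols} grid")
        return row * self.grid_cols + col


def expression_channel_count(config: ExperimentConfig) -> int:
    """Number of expression channels (reference and membrane roles excluded)."""
    return sum(1 for ch in config.channels if ch.role == "expression")


def tile_physical_position(
    config: ExperimentConfig, region: int, row: int, col: int
) -> tuple[int, int]:
    """Top-left corner of a tile in region pixel coordinates.

    Overlap is one-sided (trailing edge): each tile advances by
    ``tile_size - overlap`` along its axis.
    """
    if not 0 <= region < config.n_regions:
        raise IndexError(f"region {region} out of range [0, {config.n_regions})")
    if not 0 <= row < config.grid_rows:
        raise IndexError(f"row {row} out of range [0, {config.grid_rows})")
    if not 0 <= col < config.grid_cols:
        raise IndexError(f"col {col} out of range [0, {config.grid_cols})")
    return (
        row * (config.tile_height - config.overlap_y),
        col * (config.tile_width - config.overlap_x),
    )


# ---------------------------------------------------------------------------
# serialization

_REQUIRED_DIMENSIONS = (
    "regions", "grid_rows", "grid_cols", "cycles", "z_planes",
    "channels_per_cycle", "tile_height", "tile_width",
)
_REQUIRED_MICROSCOPE = (
    "objective_na", "magnification", "immersion_ri", "sample_ri",
    "lateral_pixel_size_um", "axial_step_um",
)


def serialize(config: ExperimentConfig) -> dict:
    """Plain-dict (YAML-ready) form of a configuration; inverse of load."""
    return {
        "schema_version": config.schema_version,
        "dimensions": {
            "regions": config.n_regions,
            "grid_rows": config.grid_rows,
            "grid_cols": config.grid_cols,
            "cycles": config.n_cycles,
            "z_planes": config.n_z,
            "channels_per_cycle": config.channels_per_cycle,
            "tile_height": config.tile_height,
            "tile_width": config.tile_width,
            "overlap_y": config.overlap_y,
            "overlap_x": config.overlap_x,
        },
        "microscope": {
            "objective_na": config.objective_na,
            "magnification": config.magnification,
            "immersion_ri": config.immersion_ri,
            "sample_ri": config.sample_ri,
            "lateral_pixel_size_um": config.lateral_pixel_size_um,
            "axial_step_um": config.axial_step_um,
        },
        "channels": [
            {
                "name": ch.name,
                "role": ch.role,
                "emission_wavelength_nm": ch.emission_wavelength_nm,
            }
            for ch in sorted(
                config.channels,
                key=lambda c: (c.cycle_index, c.channel_index_in_cycle),
            )
        ],
        "filenames": {
            "template": config.filename_template,
            "index_base": config.index_base,
        },
        "operations": copy.deepcopy(config.op_params),
        "commands": copy.deepcopy(config.commands),
        "allow_small_tiles": config.allow_small_tiles,
    }


def to_yaml(config: ExperimentConfig) -> str:
    return yaml.safe_dump(serialize(config), sort_keys=False)


def save_config(config: ExperimentConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(to_yaml(config))


def load_config(source: Any) -> ExperimentConfig:
    """Build a validated :class:`ExperimentConfig`.

    ``source`` may be a mapping (already-parsed document), a YAML string, a
    path to a YAML/JSON file, or an open text stream.  The channel table is
    listed in acquisition order; cycle and in-cycle indices are assigned from
    that order using ``channels_per_cycle``.
    """
    doc = _coerce_document(source)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"configuration document must be a mapping, got {type(doc)}")

    for section in ("dimensions", "microscope", "channels"):
        if section not in doc:
            raise MissingKeyError(f"missing required section {section!r}")
    dims = doc["dimensions"]
    for key in _REQUIRED_DIMENSIONS:
        if key not in dims:
            raise MissingKeyError(f"missing required key dimensions.{key}")
    mic = doc["microscope"]
    for key in _REQUIRED_MICROSCOPE:
        if key not in mic:
            raise MissingKeyError(f"missing required key microscope.{key}")

    n_cycles = int(dims["cycles"])
    cpc = int(dims["channels_per_cycle"])
    raw_channels = doc["channels"]
    channels = []
    for i, entry in enumerate(raw_channels):
        if "name" not in entry:
            raise MissingKeyError(f"channels[{i}] missing required key 'name'")
        channels.append(
            ChannelSpec(
                cycle_index=int(entry.get("cycle", i // max(cpc, 1))),
                channel_index_in_cycle=int(entry.get("index", i % max(cpc, 1))),
                name=str(entry["name"]),
                role=str(entry.get("role", "expression")),
                emission_wavelength_nm=float(entry.get("emission_wavelength_nm", 525.0)),
            )
        )

    op_params = _default_op_params()
    _deep_update(op_params, doc.get("operations") or {})
    filenames = doc.get("filenames") or {}

    config = ExperimentConfig(
        n_regions=int(dims["regions"]),
        grid_rows=int(dims["grid_rows"]),
        grid_cols=int(dims["grid_cols"]),
        n_cycles=n_cycles,
        n_z=int(dims["z_planes"]),
        channels_per_cycle=cpc,
        tile_height=int(dims["tile_height"]),
        tile_width=int(dims["tile_width"]),
        overlap_y=int(dims.get("overlap_y", 0)),
        overlap_x=int(dims.get("overlap_x", 0)),
        objective_na=float(mic["objective_na"]),
        magnification=float(mic["magnification"]),
        immersion_ri=float(mic["immersion_ri"]),
        sample_ri=float(mic["sample_ri"]),
        lateral_pixel_size_um=float(mic["lateral_pixel_size_um"]),
        axial_step_um=float(mic["axial_step_um"]),
        channels=tuple(channels),
        op_params=op_params,
        commands=dict(doc.get("commands") or {}),
        filename_template=str(filenames.get("template", DEFAULT_FILENAME_TEMPLATE)),
        index_base=int(filenames.get("index_base", 1)),
        allow_small_tiles=bool(doc.get("allow_small_tiles", False)),
        schema_version=int(doc.get("schema_version", SCHEMA_VERSION)),
    )
    return config.validate()


def _coerce_document(source: Any) -> Any:
    if isinstance(source, Mapping):
        return copy.deepcopy(dict(source))
    if isinstance(source, (str, os.PathLike)):
        text = str(source)
        if isinstance(source, os.PathLike) or (
            "\n" not in text and os.path.exists(text)
        ):
            with open(source) as fh:
                return yaml.safe_load(fh)
        return yaml.safe_load(io.StringIO(text))
    if hasattr(source, "read"):
        return yaml.safe_load(source)
    raise ConfigError(f"cannot interpret configuration source of type {type(source)}")


def _deep_update(base: dict, overrides: Mapping) -> dict:
    for key, value in overrides.items():
        if isinstance(value, Mapping) and isinstance(base.get(key), dict):
            _deep_update(base[key], value)
        else:
            base[key] = copy.deepcopy(value)
    return base


# ---------------------------------------------------------------------------
# deltas

def apply_delta(
    base: ExperimentConfig, delta: Mapping[str, Any]
) -> ExperimentConfig:
    """Apply dotted-path overrides to a configuration and re-validate.

    Overrides are applied to the serialized form in mapping order
    (last write wins).  Paths may index lists numerically
    (``channels.2.name``).  Unknown paths raise :class:`DeltaError`, except
    under ``operations`` where new keys may be created so pluggable
    operations can carry arbitrary parameters.
    """
    doc = serialize(base)
    for path, value in delta.items():
        _set_path(doc, path, value)
    return load_config(doc)


def merge_deltas(*deltas: Mapping[str, Any]) -> dict:
    """Merge sequential deltas into one map; later deltas win on shared paths."""
    merged: dict = {}
    for d in deltas:
        merged.update(d)
    return merged


def _set_path(doc: Any, path: str, value: Any) -> None:
    parts = path.split(".")
    node = doc
    creatable = parts[0] == "operations"
    for i, part in enumerate(parts[:-1]):
        node = _descend(node, part, path, create=creatable)
    leaf = parts[-1]
    if isinstance(node, list):
        idx = _list_index(leaf, node, path)
        node[idx] = value
    elif isinstance(node, dict):
        if leaf not in node and not creatable:
            raise DeltaError(
                f"delta path {path!r}: key {leaf!r} does not exist "
                "(new keys may only be created under 'operations')"
            )
        node[leaf] = value
    else:
        raise DeltaError(f"delta path {path!r}: cannot descend into {type(node)}")


def _descend(node: Any, part: str, path: str, create: bool) -> Any:
    if isinstance(node, list):
        return node[_list_index(part, node, path)]
    if isinstance(node, dict):
        if part not in node:
            if create:
                node[part] = {}
            else:
                raise DeltaError(f"delta path {path!r}: key {part!r} does not exist")
        return node[part]
    raise DeltaError(f"delta path {path!r}: cannot descend into {type(node)}")


def _list_index(part: str, node: list, path: str) -> int:
    try:
        idx = int(part)
    except ValueError:
        raise DeltaError(f"delta path {path!r}: {part!r} is not a list index") from None
    if not -len(node) <= idx < len(node):
        raise DeltaError(f"delta path {path!r}: index {idx} out of range")
    return idx


def diff_configs(a: ExperimentConfig, b: ExperimentConfig) -> dict[str, tuple]:
    """Dotted-path map of differing leaves between two configurations."""
    out: dict[str, tuple] = {}
    _diff(serialize(a), serialize(b), "", out)
    return out


def _diff(a: Any, b: Any, prefix: str, out: dict) -> None:
    if isinstance(a, dict) and isinstance(b, dict):
        for key in sorted(set(a) | set(b)):
            sub = f"{prefix}.{key}" if prefix else str(key)
            if key not in a:
                out[sub] = (None, b[key])
            elif key not in b:
                out[sub] = (a[key], None)
            else:
                _diff(a[key], b[key], sub, out)
    elif isinstance(a, list) and isinstance(b, list):
        for i in range(max(len(a), len(b))):
            sub = f"{prefix}.{i}"
            if i >= len(a):
                out[sub] = (None, b[i])
            elif i >= len(b):
                out[sub] = (a[i], None)
            else:
                _diff(a[i], b[i], sub, out)
    elif a != b:
        out[prefix] = (a, b)
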