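"""Raw-file naming, tile assembly, bounded prefetch and hyperstack I/O.

Raw acquisitions arrive as one 8- or 16-bit grayscale 2-D image per
(region, tile, cycle, z, channel), with the indices encoded in the file name
by a configurable template.  This module turns those files into 5-D tile
volumes ordered (cycle, z, channel, y, x), streams them through a bounded
prefetch queue, and reads/writes ImageJ-compatible TIFF hyperstacks.
"""

from __future__ import annotations

import os
import queue
import re
import threading
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
import tifffile

from .config import ExperimentConfig

_PLACEHOLDER_RE = re.compile(r"\{(region|tile|row|col|cycle|z|channel)(?::(0?)(\d+)d)?\}")

_ALLOWED_DTYPES = (np.uint8, np.uint16)


class ParseError(ValueError):
    """A file name does not match the configured pattern."""


class AssemblyError(RuntimeError):
    """Files required to assemble a tile volume are missing."""


class FormatError(ValueError):
    """An input image has the wrong shape, size or bit depth."""


@dataclass(frozen=True)
class FileNamePattern:
    """Template-driven mapping between index tuples and raw file names.

    The template uses ``{region}``, ``{tile}`` (or ``{row}``/``{col}``),
    ``{cycle}``, ``{z}`` and ``{channel}`` placeholders, each optionally with
    a zero-padding width (``{tile:03d}``).  ``index_base`` is the base used
    *in the file names*; all indices passed in and out of this class are
    0-based.
    """

    template: str
    index_base: int = 1

    def __post_init__(self) -> None:
        names = [m.group(1) for m in _PLACEHOLDER_RE.finditer(self.template)]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ParseError(f"placeholder(s) {sorted(dupes)} appear more than once "
                             f"in template {self.template!r}")
        if self.index_base not in (0, 1):
            raise ParseError(f"index_base must be 0 or 1, got {self.index_base}")

    @property
    def fields(self) -> tuple[str, ...]:
        return tuple(m.group(1) for m in _PLACEHOLDER_RE.finditer(self.template))

    def format(self, **indices: int) -> str:
        """Render a file name from 0-based indices."""
        shifted = {k: v + self.index_base for k, v in indices.items()}
        try:
            return self.template.format(**shifted)
        except KeyError as exc:
            raise ParseError(f"template {self.template!r} needs index {exc}") from None

    def _regex(self) -> re.Pattern:
        out = []
        pos = 0
        for m in _PLACEHOLDER_RE.finditer(self.template):
            out.append(re.escape(self.template[pos:m.start()]))
            width = m.group(3)
            if width:
                out.append(f"(?P<{m.group(1)}>\\d{{{int(width)},}})")
            else:
                out.append(f"(?P<{m.group(1)}>\\d+)")
            pos = m.end()
        out.append(re.escape(self.template[pos:]))
        return re.compile("".join(out))

    def parse(self, name: str) -> dict[str, int]:
        """Extract 0-based indices from a file name."""
        m = self._regex().fullmatch(name)
        if m is None:
            raise ParseError(
                f"file name {name!r} does not match pattern {self.template!r}"
            )
        return {k: int(v) - self.index_base for k, v in m.groupdict().items()}


def parse_filename(name: str, pattern: FileNamePattern) -> dict[str, int]:
    """Module-level convenience wrapper around :meth:`FileNamePattern.parse`."""
    return pattern.parse(name)


@dataclass
class TileVolume:
    """One tile's 5-D intensity array, ordered (cycle, z, channel, y, x)."""

    data: np.ndarray
    region: int = 0
    tile: int = 0
    dtype_in: np.dtype | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise FormatError(f"tile volume must be 5-D, got {self.data.ndim}-D")
        if self.dtype_in is None:
            self.dtype_in = self.data.dtype

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def pattern_from_config(config: ExperimentConfig) -> FileNamePattern:
    return FileNamePattern(config.filename_template, config.index_base)


def _tile_name_indices(config: ExperimentConfig, pattern: FileNamePattern,
                       region: int, tile: int) -> dict[str, int]:
    idx: dict[str, int] = {"region": region}
    if "tile" in pattern.fields:
        idx["tile"] = tile
    row, col = config.tile_row_col(tile)
    if "row" in pattern.fields:
        idx["row"] = row
    if "col" in pattern.fields:
        idx["col"] = col
    return idx


def read_plane(path: str | os.PathLike) -> np.ndarray:
    """Read one 2-D grayscale plane (TIFF, or PNG as a convenience)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(f"{path.name}: expected a 2-D grayscale image, "
                          f"got shape {arr.shape}")
    if arr.dtype not in _ALLOWED_DTYPES:
        raise FormatError(f"{path.name}: dtype {arr.dtype} not supported; "
                          "inputs must be unsigned 8- or 16-bit")
    return arr


def assemble_tile(
    data_dir: str | os.PathLike,
    config: ExperimentConfig,
    region: int,
    tile: int,
    pattern: FileNamePattern | None = None,
    allow_missing: bool = False,
) -> TileVolume:
    """Assemble all raw planes of one tile into a 5-D volume.

    Pixel values are preserved bit-exactly.  Missing files abort with an
    :class:`AssemblyError` listing every absent index tuple, unless
    ``allow_missing`` fills those planes with zeros.
    """
    data_dir = Path(data_dir)
    if pattern is None:
        pattern = pattern_from_config(config)
    base_idx = _tile_name_indices(config, pattern, region, tile)

    shape = (config.n_cycles, config.n_z, config.channels_per_cycle,
             config.tile_height, config.tile_width)
    data: np.ndarray | None = None
    missing: list[tuple[int, int, int]] = []
    for c in range(config.n_cycles):
        for z in range(config.n_z):
            for ch in range(config.channels_per_cycle):
                name = pattern.format(cycle=c, z=z, channel=ch, **base_idx)
                path = data_dir / name
                if not path.exists():
                    missing.append((c, z, ch))
                    continue
                plane = read_plane(path)
                if plane.shape != (config.tile_height, config.tile_width):
                    raise FormatError(
                        f"{name}: shape {plane.shape} != configured "
                        f"({config.tile_height}, {config.tile_width})"
                    )
                if data is None:
                    data = np.zeros(shape, dtype=plane.dtype)
                elif plane.dtype != data.dtype:
                    raise FormatError(
                        f"{name}: dtype {plane.dtype} differs from earlier "
                        f"planes ({data.dtype})"
                    )
                data[c, z, ch] = plane
    if missing and not allow_missing:
        raise AssemblyError(
            f"region {region} tile {tile}: {len(missing)} missing plane(s) "
            f"(cycle, z, channel): {missing[:10]}"
            + (" ..." if len(missing) > 10 else "")
        )
    if data is None:
        data = np.zeros(shape, dtype=np.uint16)
    return TileVolume(data=data, region=region, tile=tile)


def check_data_dir(
    data_dir: str | os.PathLike,
    config: ExperimentConfig,
    pattern: FileNamePattern | None = None,
) -> dict:
    """Diagnostic scan: which expected files are missing, which are extra."""
    data_dir = Path(data_dir)
    if pattern is None:
        pattern = pattern_from_config(config)
    expected = set()
    for region in range(config.n_regions):
        for tile in range(config.n_tiles):
            base_idx = _tile_name_indices(config, pattern, region, tile)
            for c in range(config.n_cycles):
                for z in range(config.n_z):
                    for ch in range(config.channels_per_cycle):
                        expected.add(pattern.format(cycle=c, z=z, channel=ch,
                                                    **base_idx))
    present = {p.name for p in data_dir.iterdir() if p.is_file()}
    return {
        "expected": len(expected),
        "missing": sorted(expected - present),
        "unrecognized": sorted(present - expected),
    }


def prefetch_tiles(
    data_dir: str | os.PathLike,
    config: ExperimentConfig,
    queue_capacity: int = 1,
    regions: Sequence[int] | None = None,
    tiles: Sequence[int] | None = None,
    loader: Callable[..., TileVolume] | None = None,
) -> Iterator[TileVolume]:
    """Yield tile volumes in row-major (region, tile) order with bounded lookahead.

    A background thread assembles tiles ahead of consumption, but never holds
    more than ``queue_capacity`` assembled-but-unconsumed volumes: assembly of
    tile ``k + queue_capacity`` does not begin before tile ``k`` is consumed.
    The yielded sequence is identical to sequential :func:`assemble_tile`
    calls for any capacity.  Assembly errors surface at the point of
    consumption.
    """
    if queue_capacity < 1:
        raise ValueError(f"queue_capacity must be >= 1, got {queue_capacity}")
    if loader is None:
        loader = assemble_tile
    region_list = list(regions) if regions is not None else list(range(config.n_regions))
    tile_list = list(tiles) if tiles is not None else list(range(config.n_tiles))
    order = [(r, t) for r in region_list for t in tile_list]

    slots = threading.Semaphore(queue_capacity)
    results: queue.Queue = queue.Queue()
    _SENTINEL = object()

    def worker() -> None:
        for r, t in order:
            slots.acquire()  # wait for a free slot *before* assembling
            try:
                vol = loader(data_dir, config, r, t)
            except BaseException as exc:  # noqa: BLE001 - re-raised at consumer
                results.put(("error", exc))
                return
            results.put(("ok", vol))
        results.put(("done", _SENTINEL))

    thread = threading.Thread(target=worker, daemon=True)
    thread.start()
    try:
        while True:
            kind, payload = results.get()
            if kind == "done":
                return
            if kind == "error":
                raise payload
            yield payload
            slots.release()
    finally:
        thread.join(timeout=0.1)


# ---------------------------------------------------------------------------
# hyperstack I/O

_CHANNEL_INFO_KEY = "cytotile_channels"


def _to_5d(data: np.ndarray) -> np.ndarray:
    """Promote a 2..5-D array to (T=cycle, Z, C, Y, X)."""
    if data.ndim < 2 or data.ndim > 5:
        raise FormatError(f"cannot interpret {data.ndim}-D array as a hyperstack")
    while data.ndim < 5:
        data = data[np.newaxis]
    return data


def write_hyperstack(
    volume: TileVolume | np.ndarray,
    path: str | os.PathLike,
    channel_names: Sequence[str] | None = None,
) -> None:
    """Write an ImageJ-compatible TIFF hyperstack.

    Dimension mapping: cycles -> frames (T), z -> slices (Z),
    channels -> channels (C).  Channel names are stored in the ImageJ
    ``Info`` metadata and recovered by :func:`read_hyperstack`.
    """
    data = volume.data if isinstance(volume, TileVolume) else np.asarray(volume)
    if data.size == 0:
        raise FormatError("refusing to write an empty hyperstack")
    if data.ndim == 2:
        # single plane -> plain single-page ImageJ TIFF
        tifffile.imwrite(path, data, imagej=True)
        return
    data5 = _to_5d(data)
    if data5.dtype not in (np.uint8, np.uint16, np.float32):
        data5 = data5.astype(np.float32)
    metadata: dict = {"axes": "TZCYX"}
    if channel_names is not None:
        if len(channel_names) != data5.shape[2]:
            raise FormatError(
                f"{len(channel_names)} channel names for {data5.shape[2]} channels"
            )
        metadata["Info"] = f"{_CHANNEL_INFO_KEY}=" + ",".join(channel_names)
    tifffile.imwrite(path, data5, imagej=True, metadata=metadata)


def read_hyperstack(path: str | os.PathLike) -> tuple[np.ndarray, list[str] | None]:
    """Read a hyperstack back as a 5-D (T, Z, C, Y, X) array plus channel names."""
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes
        names: list[str] | None = None
        meta = tif.imagej_metadata or {}
        info = meta.get("Info", "")
        for line in str(info).splitlines():
            if line.startswith(f"{_CHANNEL_INFO_KEY}="):
                names = line.split("=", 1)[1].split(",")
    # map whatever axes tifffile reports onto TZCYX
    for ax in [a for a in axes if a not in "TZCYX"]:
        i = axes.index(ax)
        if arr.shape[i] != 1:
            raise FormatError(f"unsupported non-trivial axis {ax!r} in {path}")
        arr = arr.take(0, axis=i)
        axes = axes.replace(ax, "")
    for ax in "TZCYX":
        if ax not in axes:
            arr = np.expand_dims(arr, 0)
            axes = ax + axes
    arr = np.transpose(arr, [axes.index(ax) for ax in "TZCYX"])
    return arr, names
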