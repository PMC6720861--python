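"""Fixed-order, per-tile pipeline orchestration.

Operations run in a predetermined order regardless of how flags are given:
assemble -> register -> deconvolve -> quality -> segment -> quantify ->
export.  Each can be toggled from the experiment configuration (or CLI
overrides), subject to prerequisites: everything needs assembly, segment
needs the quality stage's best-z choice, quantify needs segmentation,
export needs quantification.  The effective (delta-applied) configuration
is materialized into the output tree with every run so results are
reproducible from the outputs alone.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from . import config as cfg
from .config import ExperimentConfig
from .deconvolution import PsfParameters, PsfVolume, gibson_lanni_psf, richardson_lucy
from .extraction import export_cell_data
from .focus import best_z_for_tile
from .quantification import CellRecord, measure_cells
from .registration import register_cycles
from .segmentation import (
    LabelImage,
    default_probability_map,
    nuclei_from_probabilities,
    remove_border_cells,
    segment_cells,
)
from .tile_io import TileVolume, prefetch_tiles, write_hyperstack

OP_ORDER = ("assemble", "register", "deconvolve", "quality", "segment",
            "quantify", "export")

_PREREQS = {
    "register": ("assemble",),
    "deconvolve": ("assemble",),
    "quality": ("assemble",),
    "segment": ("assemble", "quality"),
    "quantify": ("segment",),
    "export": ("quantify",),
}


class PlanError(ValueError):
    """The enabled operation set violates prerequisites."""


@dataclass
class PipelineRun:
    """One pipeline invocation: configuration, paths and operation toggles."""

    config: ExperimentConfig
    data_dir: Path
    output_dir: Path
    enabled_ops: tuple[str, ...] = OP_ORDER
    regions: Sequence[int] | None = None
    tiles: Sequence[int] | None = None
    queue_capacity: int = 1
    skip_failed_tiles: bool = False
    log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data_dir = Path(self.data_dir)
        self.output_dir = Path(self.output_dir)
        unknown = set(self.enabled_ops) - set(OP_ORDER)
        if unknown:
            raise PlanError(f"unknown operation(s): {sorted(unknown)}")
        # canonical execution order, independent of the order flags were given
        self.enabled_ops = tuple(op for op in OP_ORDER if op in self.enabled_ops)
        for op in self.enabled_ops:
            missing = [p for p in _PREREQS.get(op, ()) if p not in self.enabled_ops]
            if missing:
                raise PlanError(f"operation {op!r} requires {missing}")


def ops_from_config(config: ExperimentConfig) -> tuple[str, ...]:
    """Derive the enabled-operation set from configuration flags."""
    p = config.op_params
    ops = ["assemble"]
    if p.get("registration", {}).get("enabled", True):
        ops.append("register")
    if p.get("deconvolution", {}).get("enabled", False):
        ops.append("deconvolve")
    if p.get("quality", {}).get("enabled", True):
        ops.append("quality")
    if p.get("segmentation", {}).get("enabled", True):
        ops += ["segment"]
    if p.get("quantification", {}).get("enabled", True) and "segment" in ops:
        ops += ["quantify", "export"]
    return tuple(ops)


class _PsfCache:
    """One PSF per emission wavelength; identical across tiles by construction."""

    def __init__(self, config: ExperimentConfig):
        self.config = config
        self._cache: dict[float, PsfVolume] = {}

    def get(self, wavelength_nm: float) -> PsfVolume:
        if wavelength_nm not in self._cache:
            ch = next(c for c in self.config.channels
                      if c.emission_wavelength_nm == wavelength_nm)
            params = PsfParameters.from_config(self.config, ch)
            self._cache[wavelength_nm] = gibson_lanni_psf(params)
        return self._cache[wavelength_nm]


def _deconvolve_volume(
    volume: TileVolume, config: ExperimentConfig, psfs: _PsfCache
) -> TileVolume:
    n_iter = int(config.op_params.get("deconvolution", {}).get("iterations", 10))
    data = volume.data.astype(np.float64)
    out = data.copy()
    for ch in config.channels:
        psf = psfs.get(ch.emission_wavelength_nm)
        stack = data[ch.cycle_index, :, ch.channel_index_in_cycle]
        out[ch.cycle_index, :, ch.channel_index_in_cycle] = richardson_lucy(
            stack, psf, n_iter=n_iter
        )
    return TileVolume(data=out.astype(np.float32), region=volume.region,
                      tile=volume.tile, dtype_in=volume.dtype_in)


def _segment_tile(
    volume: TileVolume, config: ExperimentConfig, best_z: int
) -> tuple[LabelImage, LabelImage]:
    seg = config.op_params.get("segmentation", {})
    ref = config.reference_channel(0)
    nuclear_plane = volume.data[ref.cycle_index, best_z, ref.channel_index_in_cycle]
    prob = default_probability_map(
        nuclear_plane, smoothing_sigma=float(seg.get("smoothing_sigma", 2.0))
    )
    nuclei = nuclei_from_probabilities(
        prob, min_size=int(seg.get("min_nucleus_size", 40))
    )
    mode = seg.get("cell_mode", "radius")
    membrane = None
    mem_name = seg.get("membrane_channel")
    if mem_name:
        mch = config.find_channel(mem_name)
        membrane = volume.data[mch.cycle_index, best_z, mch.channel_index_in_cycle]
    cells = segment_cells(
        nuclei, mode, membrane_image=membrane,
        radius=float(seg.get("radius", 5.0)),
        lam=float(seg.get("lambda", 1.0)),
        smoothing_sigma=float(seg.get("smoothing_sigma", 2.0)),
    )
    if seg.get("exclude_border_cells", False):
        cells, nuclei = remove_border_cells(cells, nuclei)
    return nuclei, cells


def run_pipeline(run: PipelineRun) -> list[CellRecord]:
    """Execute the pipeline, writing the output tree; returns all cell records.

    Output layout (under ``run.output_dir``)::

        config.yaml                      effective configuration
        log.jsonl                        one entry per tile
        shifts.csv                       per-(region, tile, cycle) drift table
        best_z.csv                       per-tile best-focus plane
        R{r}_T{t}/volume.tif             processed hyperstack
        R{r}_T{t}/nuclei.tif, cells.tif  16-bit label images
        R{r}_T{t}/cells.csv              per-tile cell table
        cells.csv, cells.fcs             aggregated cell table
    """
    config = run.config.validate()
    out_root = run.output_dir
    out_root.mkdir(parents=True, exist_ok=True)
    cfg.save_config(config, out_root / "config.yaml")

    ops = set(run.enabled_ops)
    psfs = _PsfCache(config) if "deconvolve" in ops else None
    all_records: list[CellRecord] = []
    shift_rows: list[dict] = []
    best_z_rows: list[dict] = []

    tiles_iter = prefetch_tiles(
        run.data_dir, config, run.queue_capacity,
        regions=run.regions, tiles=run.tiles,
    )
    for volume in tiles_iter:
        t0 = time.perf_counter()
        entry: dict = {"region": volume.region, "tile": volume.tile}
        try:
            if "register" in ops and config.n_cycles > 1:
                volume, shifts = register_cycles(volume, config)
                for s in shifts:
                    shift_rows.append({
                        "region": volume.region, "tile": volume.tile,
                        "cycle": s.cycle, "dy": s.dy, "dx": s.dx,
                        "error": s.error, "degenerate": s.degenerate,
                    })
                entry["shifts"] = [(s.cycle, s.dy, s.dx) for s in shifts]
            if "deconvolve" in ops:
                volume = _deconvolve_volume(volume, config, psfs)
            best_z = best_z_for_tile(volume, config) if "quality" in ops else 0
            entry["best_z"] = best_z
            best_z_rows.append({"region": volume.region, "tile": volume.tile,
                                "best_z": best_z})

            tile_dir = out_root / f"R{volume.region}_T{volume.tile:03d}"
            tile_dir.mkdir(exist_ok=True)
            write_hyperstack(volume, tile_dir / "volume.tif",
                             channel_names=None)

            if "segment" in ops:
                nuclei, cells = _segment_tile(volume, config, best_z)
                tifffile.imwrite(tile_dir / "nuclei.tif",
                                 nuclei.labels.astype(np.uint16))
                tifffile.imwrite(tile_dir / "cells.tif",
                                 cells.labels.astype(np.uint16))
                entry["n_cells"] = len(cells.label_set)
                if "quantify" in ops:
                    records = measure_cells(cells, nuclei, volume, best_z, config)
                    export_cell_data(records, "csv", tile_dir / "cells.csv")
                    all_records.extend(records)
        except Exception as exc:  # noqa: BLE001
            entry["error"] = repr(exc)
            run.log.append(entry)
            if run.skip_failed_tiles:
                continue
            _write_sidecars(out_root, run, shift_rows, best_z_rows)
            raise
        entry["seconds"] = round(time.perf_counter() - t0, 4)
        run.log.append(entry)

    _write_sidecars(out_root, run, shift_rows, best_z_rows)
    if "export" in ops:
        export_cell_data(all_records, "csv", out_root / "cells.csv")
        export_cell_data(all_records, "fcs", out_root / "cells.fcs")
    return all_records


def _write_sidecars(out_root: Path, run: PipelineRun,
                    shift_rows: list[dict], best_z_rows: list[dict]) -> None:
    with open(out_root / "log.jsonl", "w") as fh:
        for entry in run.log:
            fh.write(json.dumps(entry) + "\n")
    if shift_rows:
        _write_csv(out_root / "shifts.csv", shift_rows)
    if best_z_rows:
        _write_csv(out_root / "best_z.csv", best_z_rows)


def _write_csv(path: Path, rows: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
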