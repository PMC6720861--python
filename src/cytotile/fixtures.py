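"""Synthetic raw experiments with known ground truth.

Generates a full raw file tree — one 16-bit grayscale TIFF per (region,
tile, cycle, z, channel) following the configured file-name pattern — from a
simple cell model, so every pipeline stage can be exercised and checked
against truth without any downloads:

* nuclei are isotropic Gaussian intensity profiles at non-overlapping
  random centers (a minimum center spacing is enforced by construction);
* the membrane channel renders a ring at each cell radius;
* expression channels render a constant per-cell level over the cell disc;
* axial structure is a Gaussian focus falloff around a mid-stack focal
  plane, so best-z selection has signal;
* per-cycle drift translates the whole scene by a per-cycle offset
  (cycle 0 is never drifted), optionally fractional;
* optional Gaussian blur, Poisson shot noise and additive Gaussian read
  noise, then 16-bit quantization.

One integer seed drives all randomness; regeneration is byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .config import ExperimentConfig
from .tile_io import pattern_from_config, _tile_name_indices


class GenerationError(RuntimeError):
    """The requested cell density cannot satisfy the spacing constraint."""


@dataclass
class GenerationParams:
    """Knobs of the synthetic scene.

    Intensities are on a unit scale before quantization;
    ``intensity_scale`` maps 1.0 to that many 16-bit counts.
    """

    cells_per_tile: int = 15
    nucleus_radius: tuple[float, float] = (4.0, 6.0)
    cell_radius: tuple[float, float] = (9.0, 12.0)
    nuclear_level: tuple[float, float] = (0.55, 0.9)
    expression_level: tuple[float, float] = (0.2, 0.9)
    membrane_level: tuple[float, float] = (0.4, 0.8)
    background: float = 0.02
    drift_max: float = 0.0          # per-cycle |drift| bound, pixels
    integer_drift: bool = True
    blur_sigma: float = 0.0         # lateral Gaussian blur, pixels
    defocus_blur_per_plane: float = 1.5  # extra blur sigma per plane off focus
    gaussian_noise_sd: float = 0.0  # additive, unit scale
    poisson_photons: float = 0.0    # >0 enables shot noise at this photon budget
    axial_sigma_planes: float = 0.0 # 0 -> derived as n_z / 4
    edge_margin: float = 2.0        # clearance between cells, pixels
    intensity_scale: float = 20000.0


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    cells: pd.DataFrame          # per-cell geometry and true channel levels
    drifts: dict[int, tuple[float, float]]   # cycle -> (dy, dx) applied
    focus_z: int
    seed: int
    params: GenerationParams

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def expected_registration_shift(self, cycle: int) -> tuple[float, float]:
        """The translation registration should apply to re-align a cycle."""
        dy, dx = self.drifts.get(cycle, (0.0, 0.0))
        return (-dy, -dx)

    def save_csv(self, path: str | os.PathLike) -> None:
        self.cells.to_csv(path, index=False)


def _sample_centers(
    rng: np.random.Generator,
    n: int,
    height: int,
    width: int,
    min_spacing: float,
    border: float,
    max_tries: int = 400,
) -> np.ndarray:
    """Rejection-sample ``n`` centers at pairwise distance >= min_spacing."""
    usable = (height - 2 * border) * (width - 2 * border)
    if usable <= 0 or n * np.pi * (min_spacing / 2) ** 2 > 0.7 * usable:
        raise GenerationError(
            f"{n} cells with spacing {min_spacing:.1f} do not fit a "
            f"{height}x{width} tile"
        )
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        if tries > max_tries * n:
            raise GenerationError(
                f"placed only {len(centers)}/{n} cells after {tries} draws; "
                "density infeasible under the spacing constraint"
            )
        tries += 1
        y = rng.uniform(border, height - border)
        x = rng.uniform(border, width - border)
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_spacing**2
               for cy, cx in centers):
            centers.append((y, x))
    return np.array(centers)


def _soft_disc(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float,
               radius: float) -> np.ndarray:
    """Anti-aliased disc: 1 inside, 0 outside, 1-px linear ramp at the rim."""
    r = np.hypot(yy - cy, xx - cx)
    return np.clip(radius - r + 0.5, 0.0, 1.0)


def _soft_ring(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float,
               radius: float, thickness: float = 1.5) -> np.ndarray:
    r = np.hypot(yy - cy, xx - cx)
    return np.clip(thickness / 2 - np.abs(r - radius) + 0.5, 0.0, 1.0)


def _gaussian_blob(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float,
                   sigma: float) -> np.ndarray:
    return np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))


def generate_experiment(
    config: ExperimentConfig,
    params: GenerationParams,
    out_dir: str | os.PathLike,
    seed: int,
) -> GroundTruth:
    """Write a synthetic raw experiment to disk and return its ground truth.

    Cell geometry and expression levels are shared across cycles (the same
    specimen is imaged repeatedly); only the drift differs per cycle.
    """
    from scipy import ndimage  # local import keeps module import light

    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pattern = pattern_from_config(config)

    h, w = config.tile_height, config.tile_width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    focus_z = config.n_z // 2
    axial_sigma = params.axial_sigma_planes or max(config.n_z / 4.0, 0.75)
    z_gain = np.exp(
        -((np.arange(config.n_z) - focus_z) ** 2) / (2.0 * axial_sigma**2)
    )

    # per-cycle drift; cycle 0 anchored at zero
    drifts: dict[int, tuple[float, float]] = {0: (0.0, 0.0)}
    for c in range(1, config.n_cycles):
        dy, dx = rng.uniform(-params.drift_max, params.drift_max, size=2)
        if params.integer_drift:
            dy, dx = float(np.round(dy)), float(np.round(dx))
        drifts[c] = (dy, dx)

    min_spacing = 2 * params.cell_radius[1] + params.edge_margin
    border = params.cell_radius[1] + params.drift_max + 1

    rows: list[dict] = []
    cell_id = 0
    for region in range(config.n_regions):
        for tile in range(config.n_tiles):
            centers = _sample_centers(rng, params.cells_per_tile, h, w,
                                      min_spacing, border)
            nuc_r = rng.uniform(*params.nucleus_radius, size=len(centers))
            cell_r = rng.uniform(*params.cell_radius, size=len(centers))
            nuc_level = rng.uniform(*params.nuclear_level, size=len(centers))
            mem_level = rng.uniform(*params.membrane_level, size=len(centers))
            levels = {
                ch.name: rng.uniform(*params.expression_level, size=len(centers))
                for ch in config.channels if ch.role == "expression"
            }
            for i, (cy, cx) in enumerate(centers):
                cell_id += 1
                row = {
                    "cell_id": cell_id, "region": region, "tile": tile,
                    "y": cy, "x": cx,
                    "nucleus_radius": nuc_r[i], "cell_radius": cell_r[i],
                    "nuclear_level": nuc_level[i], "membrane_level": mem_level[i],
                }
                for name, lv in levels.items():
                    row[f"level:{name}"] = lv[i]
                rows.append(row)

            # render base (undrifted, in-focus) planes per channel role
            base_idx = _tile_name_indices(config, pattern, region, tile)
            for c in range(config.n_cycles):
                dy, dx = drifts[c]
                scene: dict[str, np.ndarray] = {}
                for ch in config.channels:
                    if ch.cycle_index != c:
                        continue
                    plane = np.zeros((h, w))
                    for i, (cy, cx) in enumerate(centers):
                        py, px = cy + dy, cx + dx
                        if ch.role == "reference":
                            plane += nuc_level[i] * _gaussian_blob(
                                yy, xx, py, px, nuc_r[i] / 1.5)
                        elif ch.role == "membrane":
                            plane += mem_level[i] * _soft_ring(
                                yy, xx, py, px, cell_r[i])
                        else:
                            plane += levels[ch.name][i] * _soft_disc(
                                yy, xx, py, px, cell_r[i])
                    scene[ch.name] = plane
                for z in range(config.n_z):
                    for ch in config.channels:
                        if ch.cycle_index != c:
                            continue
                        img = params.background + scene[ch.name] * z_gain[z]
                        # out-of-focus planes are blurred, not only dimmed,
                        # so focus scoring has signal to find the focal plane
                        defocus = params.defocus_blur_per_plane * abs(z - focus_z)
                        sigma = float(np.hypot(params.blur_sigma, defocus))
                        if sigma > 0:
                            img = ndimage.gaussian_filter(img, sigma)
                        if params.poisson_photons > 0:
                            img = rng.poisson(
                                np.clip(img, 0, None) * params.poisson_photons
                            ) / params.poisson_photons
                        if params.gaussian_noise_sd > 0:
                            img = img + rng.normal(
                                0.0, params.gaussian_noise_sd, img.shape)
                        counts = np.clip(
                            img * params.intensity_scale, 0, 65535
                        ).astype(np.uint16)
                        name = pattern.format(
                            cycle=c, z=z,
                            channel=ch.channel_index_in_cycle, **base_idx)
                        tifffile.imwrite(out_dir / name, counts)

    truth = GroundTruth(
        cells=pd.DataFrame(rows),
        drifts=drifts,
        focus_z=focus_z,
        seed=seed,
        params=params,
    )
    truth.save_csv(out_dir / "ground_truth.csv")
    return truth
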