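"""Shared fixtures: small experiment configurations and helper geometry."""

from __future__ import annotations

import numpy as np
import pytest

from cytotile import config as cfg


def make_config_doc(
    regions: int = 1,
    grid: tuple[int, int] = (1, 1),
    cycles: int = 1,
    z_planes: int = 1,
    tile: tuple[int, int] = (128, 128),
    overlap: tuple[int, int] = (0, 0),
    channels_per_cycle: int = 1,
    channel_roles: list[str] | None = None,
    operations: dict | None = None,
) -> dict:
    """Build a config document; default channel layout is reference-first."""
    if channel_roles is None:
        channel_roles = ["reference"] + ["expression"] * (channels_per_cycle - 1)
    assert len(channel_roles) == channels_per_cycle
    wavelengths = {"reference": 461.0, "expression": 525.0, "membrane": 595.0}
    channels = []
    for c in range(cycles):
        for i, role in enumerate(channel_roles):
            channels.append({
                "name": f"ch{c}_{i}",
                "role": role,
                "emission_wavelength_nm": wavelengths[role] + 10 * i,
            })
    doc = {
        "dimensions": {
            "regions": regions, "grid_rows": grid[0], "grid_cols": grid[1],
            "cycles": cycles, "z_planes": z_planes,
            "channels_per_cycle": channels_per_cycle,
            "tile_height": tile[0], "tile_width": tile[1],
            "overlap_y": overlap[0], "overlap_x": overlap[1],
        },
        "microscope": {
            "objective_na": 0.75, "magnification": 20.0,
            "immersion_ri": 1.0, "sample_ri": 1.33,
            "lateral_pixel_size_um": 0.325, "axial_step_um": 0.5,
        },
        "channels": channels,
    }
    if operations is not None:
        doc["operations"] = operations
    return doc


@pytest.fixture
def minimal_config() -> cfg.ExperimentConfig:
    """Smallest legal experiment: 1 region, 1x1 grid, 1 cycle, 1 z, 1 channel."""
    return cfg.load_config(make_config_doc())


@pytest.fixture
def small_multicycle_config() -> cfg.ExperimentConfig:
    """2 cycles x (reference + expression), 3 z, one 96x96 tile."""
    return cfg.load_config(make_config_doc(
        cycles=2, z_planes=3, tile=(96, 96), channels_per_cycle=2,
    ))


def disc_labels(shape: tuple[int, int], discs: list[tuple[float, float, float]]) -> np.ndarray:
    """Label image with one disc per (cy, cx, radius), labeled 1..K."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    out = np.zeros(shape, dtype=np.int32)
    for k, (cy, cx, r) in enumerate(discs, start=1):
        out[np.hypot(yy - cy, xx - cx) <= r] = k
    return out
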