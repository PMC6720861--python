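"""Plane quality scoring and best-focus z selection.

Each 2-D plane of a z-stack gets a sharpness score; the best-scoring plane
of the reference channel is used for 2-D segmentation and quantification.
The scorer is pluggable by name so a learned quality model can be dropped in;
the default is the variance of the discrete Laplacian of the unit-normalized
image, a classical focus metric that is exactly invariant to positive
intensity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .config import ChannelSpec, ExperimentConfig
from .tile_io import TileVolume

Scorer = Callable[[np.ndarray], float]

SCORERS: dict[str, Scorer] = {}


def register_scorer(name: str) -> Callable[[Scorer], Scorer]:
    def deco(fn: Scorer) -> Scorer:
        SCORERS[name] = fn
        return fn
    return deco


@dataclass(frozen=True)
class FocusScore:
    z: int
    score: float


@register_scorer("laplacian_variance")
def laplacian_variance(image: np.ndarray) -> float:
    """Variance of the Laplacian of the min-max normalized image.

    Constant images score exactly 0.  Normalizing to [0, 1] first makes the
    score invariant under ``a * I + b`` for a > 0, so planes are comparable
    regardless of exposure scaling.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("focus scoring expects a 2-D image of at least 3x3")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return 0.0
    norm = (img - lo) / (hi - lo)
    lap = ndimage.laplace(norm)
    return float(lap.var())


@register_scorer("log_variance")
def log_variance(image: np.ndarray) -> float:
    """Variance of the Laplacian-of-Gaussian (sigma = 2 px) of the standardized image.

    The pre-smoothing suppresses per-pixel shot/read noise, which otherwise
    dominates derivative-based sharpness on dim, low-contrast planes; the
    mean/std standardization keeps the score exactly invariant under
    ``a * I + b`` for a > 0.  This is the pipeline's default best-z scorer.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("focus scoring expects a 2-D image of at least 3x3")
    sd = img.std()
    if sd == 0:
        return 0.0
    norm = (img - img.mean()) / sd
    return float(ndimage.gaussian_laplace(norm, 2.0).var())


def score_focus(image: np.ndarray, scorer: str | Scorer = "laplacian_variance") -> float:
    fn = SCORERS[scorer] if isinstance(scorer, str) else scorer
    return fn(image)


def score_stack(
    stack: np.ndarray, scorer: str | Scorer = "laplacian_variance"
) -> list[FocusScore]:
    """Score every z-plane of a (z, y, x) stack."""
    return [FocusScore(z=z, score=score_focus(stack[z], scorer))
            for z in range(stack.shape[0])]


def select_best_z(
    volume: TileVolume | np.ndarray,
    channel: ChannelSpec | None = None,
    scorer: str | Scorer = "laplacian_variance",
) -> int:
    """Index of the sharpest z-plane for one channel; ties take the smallest z.

    ``volume`` may be a 5-D tile volume (``channel`` selects the cycle/slot)
    or a plain (z, y, x) stack.
    """
    if isinstance(volume, TileVolume):
        if channel is None:
            raise ValueError("a ChannelSpec is required with a TileVolume")
        stack = volume.data[channel.cycle_index, :, channel.channel_index_in_cycle]
    else:
        stack = np.asarray(volume)
        if stack.ndim != 3:
            raise ValueError("expected a (z, y, x) stack")
    scores = np.array([s.score for s in score_stack(stack, scorer)])
    return int(np.argmax(scores))  # argmax takes the first (smallest z) on ties


def best_z_for_tile(volume: TileVolume, config: ExperimentConfig) -> int:
    """Best-focus z of the cycle-0 reference channel, reused for all channels."""
    scorer = config.op_params.get("quality", {}).get("scorer", "log_variance")
    return select_best_z(volume, config.reference_channel(0), scorer)
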