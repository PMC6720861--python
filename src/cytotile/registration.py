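"""Per-cycle translational drift correction.

Between imaging cycles the sample drifts by a small translation.  Because a
nuclear reference channel is acquired in every cycle, the drift of cycle
``c`` can be estimated by cross-correlating the cycle-0 and cycle-``c``
reference images, and the inferred translation is then applied to every
z-plane and channel of cycle ``c``.

Shift estimation uses frequency-domain cross-correlation with optional
subpixel refinement by a locally upsampled discrete Fourier transform
(matrix-multiply DFT around the integer peak), the standard efficient
subpixel registration scheme.  Sign convention: applying the returned
(dy, dx) to the moving image aligns it to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .config import ExperimentConfig
from .tile_io import TileVolume


class DegenerateImageError(ValueError):
    """A constant image carries no registration signal."""


@dataclass(frozen=True)
class DriftShift:
    """Estimated translation for one cycle (relative to cycle 0)."""

    cycle: int
    dy: float
    dx: float
    error: float
    degenerate: bool = False


def _upsampled_dft(
    data: np.ndarray,
    upsampled_region_size: int,
    upsample_factor: int,
    axis_offsets: Sequence[float],
) -> np.ndarray:
    """Evaluate the inverse DFT of ``data`` on an upsampled local grid."""
    im2pi = 1j * 2 * np.pi
    for n_items, ax_offset in zip(data.shape[::-1], axis_offsets[::-1]):
        kernel = (np.arange(upsampled_region_size)[:, None] - ax_offset) * (
            np.fft.fftfreq(n_items, upsample_factor)
        )
        kernel = np.exp(-im2pi * kernel)
        data = np.tensordot(kernel, data, axes=(1, -1))
    return data


def _peak_with_tiebreak(cc: np.ndarray) -> tuple[int, int]:
    """Argmax of a cross-correlation surface with a deterministic tie rule.

    Among maxima equal to within a tiny relative tolerance, prefer the
    smallest |dy| + |dx|, then smallest signed dy, then smallest signed dx.
    """
    peak = cc.max()
    tol = 1e-9 * max(abs(peak), 1e-30)
    ys, xs = np.nonzero(cc >= peak - tol)
    ny, nx = cc.shape
    dys = np.where(ys > ny // 2, ys - ny, ys).astype(float)
    dxs = np.where(xs > nx // 2, xs - nx, xs).astype(float)
    order = np.lexsort((dxs, dys, np.abs(dys) + np.abs(dxs)))
    k = order[0]
    return int(dys[k]), int(dxs[k])


def estimate_shift(
    ref_image: np.ndarray,
    mov_image: np.ndarray,
    upsample_factor: int = 1,
    cycle: int = -1,
) -> DriftShift:
    """Estimate the translation aligning ``mov_image`` onto ``ref_image``.

    With ``upsample_factor`` u > 1, the integer-pixel estimate is refined to
    1/u pixel by evaluating the cross-correlation on a u-times upsampled
    grid in a small neighbourhood of the peak.
    """
    ref = np.asarray(ref_image, dtype=np.float64)
    mov = np.asarray(mov_image, dtype=np.float64)
    if ref.shape != mov.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {mov.shape}")
    if ref.ndim != 2:
        raise ValueError("estimate_shift expects 2-D images")
    if upsample_factor < 1:
        raise ValueError("upsample_factor must be >= 1")
    if np.ptp(ref) == 0 or np.ptp(mov) == 0:
        raise DegenerateImageError("constant image: drift is unidentifiable")

    f_ref = np.fft.fft2(ref)
    f_mov = np.fft.fft2(mov)
    product = f_ref * f_mov.conj()
    cc = np.fft.ifft2(product).real
    dy, dx = _peak_with_tiebreak(cc)
    shifts = np.array([dy, dx], dtype=float)

    n_pix = ref.size
    ref_amp = (np.abs(f_ref) ** 2).sum() / n_pix
    mov_amp = (np.abs(f_mov) ** 2).sum() / n_pix

    if upsample_factor == 1:
        # cc is already 1/N-normalized by the inverse FFT
        peak_val = cc[dy % cc.shape[0], dx % cc.shape[1]]
    else:
        u = int(upsample_factor)
        shifts = np.round(shifts * u) / u
        region = int(np.ceil(u * 1.5))
        dftshift = np.fix(region / 2.0)
        offsets = dftshift - shifts * u
        cc_up = _upsampled_dft(product.conj(), region, u, offsets).conj() / n_pix
        cc_up_real = cc_up.real
        iy, ix = np.unravel_index(np.argmax(cc_up_real), cc_up_real.shape)
        peak_val = cc_up_real[iy, ix]
        shifts = shifts + (np.array([iy, ix], dtype=float) - dftshift) / u

    with np.errstate(invalid="ignore"):
        err = 1.0 - peak_val**2 / max(ref_amp * mov_amp, 1e-300)
    error = float(np.sqrt(max(err, 0.0)))
    # estimated peak position is where mov content sits relative to ref;
    # the registering translation applied to mov is that displacement itself
    return DriftShift(cycle=cycle, dy=float(shifts[0]), dx=float(shifts[1]),
                      error=error)


def apply_shift(image: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Translate a 2-D image by (dy, dx), filling exposed borders with zeros.

    Integer shifts use plain array slicing (bit-exact); fractional shifts use
    a frequency-domain phase shift, with the wrapped margin zeroed.
    """
    image = np.asarray(image)
    if float(dy).is_integer() and float(dx).is_integer():
        out = np.zeros_like(image)
        idy, idx = int(dy), int(dx)
        h, w = image.shape
        ys_src = slice(max(0, -idy), min(h, h - idy))
        xs_src = slice(max(0, -idx), min(w, w - idx))
        ys_dst = slice(max(0, idy), min(h, h + idy))
        xs_dst = slice(max(0, idx), min(w, w + idx))
        out[ys_dst, xs_dst] = image[ys_src, xs_src]
        return out
    f = np.fft.fft2(image.astype(np.float64))
    shifted = np.fft.ifft2(ndimage.fourier_shift(f, (dy, dx))).real
    out = shifted.astype(np.float64)
    h, w = out.shape
    my, mx = int(np.ceil(abs(dy))), int(np.ceil(abs(dx)))
    if dy > 0:
        out[:my] = 0
    elif dy < 0 and my:
        out[-my:] = 0
    if dx > 0:
        out[:, :mx] = 0
    elif dx < 0 and mx:
        out[:, -mx:] = 0
    return out


def register_cycles(
    volume: TileVolume,
    config: ExperimentConfig,
    upsample_factor: int | None = None,
) -> tuple[TileVolume, list[DriftShift]]:
    """Register all cycles of a tile volume to cycle 0.

    Drift is estimated in 2-D between maximum-intensity z-projections of the
    reference channel of cycle 0 and cycle c, then the same translation is
    applied to every z-plane of every channel of cycle c.  Cycle 0 is
    returned bit-exactly unchanged.  Constant (degenerate) reference images
    yield a zero shift flagged ``degenerate`` rather than an error.
    """
    if upsample_factor is None:
        upsample_factor = int(
            config.op_params.get("registration", {}).get("upsample_factor", 1)
        )
    data = volume.data
    fractional = upsample_factor > 1
    out = data.astype(np.float64) if fractional else data.copy()

    ref0_ch = config.reference_channel(0).channel_index_in_cycle
    ref0 = data[0, :, ref0_ch].astype(np.float64).max(axis=0)

    shifts: list[DriftShift] = [DriftShift(cycle=0, dy=0.0, dx=0.0, error=0.0)]
    for c in range(1, config.n_cycles):
        ref_ch = config.reference_channel(c).channel_index_in_cycle
        ref_c = data[c, :, ref_ch].astype(np.float64).max(axis=0)
        try:
            shift = estimate_shift(ref0, ref_c, upsample_factor, cycle=c)
        except DegenerateImageError:
            shifts.append(DriftShift(cycle=c, dy=0.0, dx=0.0, error=float("nan"),
                                     degenerate=True))
            continue
        shifts.append(shift)
        if shift.dy == 0.0 and shift.dx == 0.0:
            continue
        for z in range(config.n_z):
            for ch in range(config.channels_per_cycle):
                plane = apply_shift(data[c, z, ch].astype(np.float64),
                                    shift.dy, shift.dx)
                if not fractional:
                    plane = np.clip(plane, 0, None).astype(data.dtype)
                out[c, z, ch] = plane
    if fractional:
        out = np.clip(out, 0, None).astype(np.float32)
        # keep cycle 0 bit-exact in value
        out[0] = data[0]
    return TileVolume(data=out, region=volume.region, tile=volume.tile,
                      dtype_in=volume.dtype_in), shifts
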