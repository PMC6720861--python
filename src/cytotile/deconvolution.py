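"""Configuration-derived PSF generation and 3-D Richardson-Lucy deconvolution.

The point spread function is the scalar-diffraction Gibson-Lanni model: the
complex field at radius r and defocus z is the pupil integral

    I(r, z) = integral_0^1  J0(k NA r rho) exp(i k W(rho; z)) rho d rho

with k = 2 pi / lambda and optical path difference

    W(rho; z) = z sqrt(ni^2 - NA^2 rho^2) + pz sqrt(ns^2 - NA^2 rho^2)

(defocus through the immersion medium of index ni plus depth pz of the
emitter inside a sample of index ns).  The PSF is |I|^2.

Rather than integrating numerically per voxel, the oscillatory phase factor
exp(i k W) is approximated, per z-plane, by a least-squares combination of
scaled Bessel functions J0(sigma_m rho); each basis term then has a closed
form radial integral, so the whole PSF reduces to a small matrix product
followed by radial interpolation onto the voxel grid.  A direct-quadrature
oracle lives in the test suite to pin the approximation's accuracy.

Richardson-Lucy restoration applies the multiplicative update

    x  <-  x * ( K^T (*) ( d / (K (*) x) ) )

with frequency-domain convolution on a reflection-padded grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib import scimath
from scipy import fft as sp_fft
from scipy import special

from .config import ExperimentConfig, ChannelSpec


class PhysicsError(ValueError):
    """Optically impossible parameter combination (e.g. NA >= all indices)."""


class PsfSizeError(ValueError):
    """PSF grid invalid (even size) or larger than the padded image."""


@dataclass(frozen=True)
class PsfParameters:
    """Optical and sampling parameters for PSF generation.

    Lengths are micrometers except the emission wavelength (nanometers,
    matching how filters are specified).  All grid sizes must be odd so the
    kernel is centred on a voxel.
    """

    objective_na: float
    emission_wavelength_nm: float
    immersion_ri: float
    sample_ri: float
    lateral_pixel_size_um: float
    axial_step_um: float
    size_z: int = 9
    size_y: int = 17
    size_x: int = 17
    particle_depth_um: float = 0.0

    def __post_init__(self) -> None:
        if not self.emission_wavelength_nm > 0:
            raise ValueError("emission wavelength must be > 0")
        if not 0 < self.objective_na < max(self.immersion_ri, self.sample_ri):
            raise PhysicsError(
                f"NA {self.objective_na} must lie in (0, max(ni, ns)="
                f"{max(self.immersion_ri, self.sample_ri)})"
            )
        for name in ("size_z", "size_y", "size_x"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise PsfSizeError(f"{name} must be odd and >= 1, got {v}")
        if self.lateral_pixel_size_um <= 0 or self.axial_step_um <= 0:
            raise ValueError("voxel sizes must be positive")

    @classmethod
    def from_config(
        cls,
        config: ExperimentConfig,
        channel: ChannelSpec,
        size_z: int | None = None,
        size_xy: int | None = None,
    ) -> "PsfParameters":
        if size_z is None:
            size_z = config.n_z if config.n_z % 2 == 1 else config.n_z - 1
            size_z = max(size_z, 1)
        if size_xy is None:
            size_xy = int(config.op_params.get("deconvolution", {})
                          .get("psf_size_xy", 17))
        return cls(
            objective_na=config.objective_na,
            emission_wavelength_nm=channel.emission_wavelength_nm,
            immersion_ri=config.immersion_ri,
            sample_ri=config.sample_ri,
            lateral_pixel_size_um=config.lateral_pixel_size_um,
            axial_step_um=config.axial_step_um,
            size_z=size_z,
            size_y=size_xy,
            size_x=size_xy,
        )


@dataclass
class PsfVolume:
    """Unit-sum, non-negative 3-D kernel ordered (z, y, x)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise PsfSizeError("PSF must be 3-D (z, y, x)")


def opd(rho: np.ndarray, z: float, params: PsfParameters) -> np.ndarray:
    """Optical path difference W(rho; z) in micrometers (complex-safe)."""
    na2rho2 = (params.objective_na * rho) ** 2
    w = z * scimath.sqrt(params.immersion_ri**2 - na2rho2)
    if params.particle_depth_um != 0.0:
        w = w + params.particle_depth_um * scimath.sqrt(
            params.sample_ri**2 - na2rho2
        )
    return w


def _field_radial(
    params: PsfParameters,
    r_um: np.ndarray,
    z_um: np.ndarray,
    num_basis: int | None = None,
    num_rho: int = 1000,
) -> np.ndarray:
    """Complex pupil-integral field sampled at radii ``r_um`` for each z.

    Returns an array of shape (len(z_um), len(r_um)).
    """
    wavelength_um = params.emission_wavelength_nm / 1000.0
    k = 2.0 * np.pi / wavelength_um
    na = params.objective_na

    # highest rho-frequency of the phase factor determines the basis size
    z_reach = float(np.max(np.abs(z_um))) + abs(params.particle_depth_um)
    denom = np.sqrt(max(params.immersion_ri**2 - na**2, 1e-3))
    f_max = k * na**2 * z_reach / denom
    if num_basis is None:
        num_basis = int(np.clip(np.ceil((f_max + 30.0) / 1.5), 60, 600))

    rho = np.linspace(0.0, 1.0, num_rho)
    sigma = 1.5 * np.arange(1, num_basis + 1) - 0.75  # spacing 1.5, offset
    basis = special.j0(np.outer(rho, sigma))  # (num_rho, num_basis)

    phases = np.empty((len(z_um), num_rho), dtype=complex)
    for i, z in enumerate(z_um):
        phases[i] = np.exp(1j * k * opd(rho, float(z), params))
    # least-squares basis coefficients, one column per z-plane
    coeffs, *_ = np.linalg.lstsq(basis, phases.T, rcond=None)

    beta = k * na * np.asarray(r_um, dtype=float)
    # closed-form integral of rho*J0(sigma rho)*J0(beta rho) over [0, 1]
    sg = sigma[:, None]
    bt = beta[None, :]
    denom2 = sg**2 - bt**2
    j0b, j1b = special.j0(bt), special.j1(bt)
    j0s, j1s = special.j0(sg), special.j1(sg)
    with np.errstate(divide="ignore", invalid="ignore"):
        radial = (sg * j1s * j0b - bt * j0s * j1b) / denom2
    # sigma == beta limit: integral of rho*J0(s rho)^2 = (J0(s)^2 + J1(s)^2)/2
    tie = np.isclose(denom2, 0.0, atol=1e-9)
    if np.any(tie):
        lim = 0.5 * (j0s**2 + j1s**2) * np.ones_like(bt)
        radial = np.where(tie, lim, radial)
    return coeffs.T @ radial  # (n_z, n_r)


def gibson_lanni_psf(params: PsfParameters) -> PsfVolume:
    """Sample the Gibson-Lanni PSF on the configured voxel grid.

    The kernel is built from a radial profile per z-plane (hence exactly
    symmetric under x and y reflection about the centre voxel) and
    normalized to unit sum.
    """
    cz, cy, cx = params.size_z // 2, params.size_y // 2, params.size_x // 2
    z_um = (np.arange(params.size_z) - cz) * params.axial_step_um
    yy = (np.arange(params.size_y) - cy) * params.lateral_pixel_size_um
    xx = (np.arange(params.size_x) - cx) * params.lateral_pixel_size_um
    rr = np.hypot(yy[:, None], xx[None, :])

    r_max = float(rr.max())
    n_r = max(2 * max(params.size_y, params.size_x), 64)
    r_samples = np.linspace(0.0, r_max + 1e-9, n_r)
    field = _field_radial(params, r_samples, z_um)
    intensity = np.abs(field) ** 2  # (n_z, n_r)

    psf = np.empty((params.size_z, params.size_y, params.size_x))
    flat_r = rr.ravel()
    for i in range(params.size_z):
        psf[i] = np.interp(flat_r, r_samples, intensity[i]).reshape(rr.shape)
    psf = np.clip(psf, 0.0, None)
    total = psf.sum()
    if total <= 0:
        raise PhysicsError("degenerate PSF: zero total intensity")
    return PsfVolume(data=psf / total)


# ---------------------------------------------------------------------------
# Richardson-Lucy

_EPS = 1e-12


def _centered_otf(psf: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Zero-pad the PSF to ``shape`` with its centre voxel moved to the origin."""
    padded = np.zeros(shape, dtype=np.float64)
    slices = tuple(slice(0, s) for s in psf.shape)
    padded[slices] = psf
    center = tuple(s // 2 for s in psf.shape)
    padded = np.roll(padded, tuple(-c for c in center), axis=tuple(range(psf.ndim)))
    return sp_fft.rfftn(padded)


def richardson_lucy(
    observed: np.ndarray,
    psf: PsfVolume | np.ndarray,
    n_iter: int = 10,
    pad_mode: str = "reflect",
) -> np.ndarray:
    """Richardson-Lucy deconvolution with frequency-domain convolution.

    The observed volume is padded by half the PSF extent per axis (default
    reflection padding) before the FFTs, so tile borders do not wrap around,
    and cropped afterwards.  ``n_iter == 0`` returns the observed volume as
    float.  The PSF is normalized internally, so the result is invariant to
    a global positive scaling of the kernel.
    """
    kernel = psf.data if isinstance(psf, PsfVolume) else np.asarray(psf, float)
    obs = np.asarray(observed, dtype=np.float64)
    if obs.ndim != kernel.ndim:
        raise ValueError(
            f"observed is {obs.ndim}-D but psf is {kernel.ndim}-D"
        )
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    if np.any(~np.isfinite(obs)) or np.any(obs < 0):
        raise ValueError("observed volume must be finite and non-negative")
    ksum = kernel.sum()
    if not np.isfinite(ksum) or ksum <= 0:
        raise ValueError("psf must have positive finite total intensity")
    kernel = kernel / ksum
    if n_iter == 0:
        return obs

    if any(k > s for k, s in zip(kernel.shape, obs.shape)):
        raise PsfSizeError(
            f"psf shape {kernel.shape} exceeds image shape {obs.shape}"
        )
    pad = tuple((p, p) for p in (s // 2 for s in kernel.shape))
    pshape = tuple(s + lo + hi for s, (lo, hi) in zip(obs.shape, pad))
    crop = tuple(slice(lo, lo + s) for s, (lo, _) in zip(obs.shape, pad))
    otf = _centered_otf(kernel, pshape)
    otf_conj = otf.conj()

    def conv(arr: np.ndarray, transfer: np.ndarray) -> np.ndarray:
        # re-padding every convolution keeps boundary handling identical to
        # a per-convolution reflective spatial filter (no wrap accumulation)
        arr_pad = np.pad(arr, pad, mode=pad_mode)
        out = sp_fft.irfftn(sp_fft.rfftn(arr_pad) * transfer, s=pshape)
        return out[crop]

    x = obs.copy()
    for _ in range(n_iter):
        model = np.clip(conv(x, otf), 0.0, None)
        ratio = obs / (model + _EPS)
        x *= conv(ratio, otf_conj)
        np.clip(x, 0.0, None, out=x)
    return x


def convolve(volume: np.ndarray, psf: PsfVolume | np.ndarray) -> np.ndarray:
    """Forward blur with the same padded frequency-domain path RL uses."""
    kernel = psf.data if isinstance(psf, PsfVolume) else np.asarray(psf, float)
    vol = np.asarray(volume, dtype=np.float64)
    pad = tuple(s // 2 for s in kernel.shape)
    mode = "reflect" if all(p <= s - 1 for p, s in zip(pad, vol.shape)) else "edge"
    vpad = np.pad(vol, tuple((p, p) for p in pad), mode=mode)
    otf = _centered_otf(kernel / kernel.sum(), vpad.shape)
    out = sp_fft.irfftn(sp_fft.rfftn(vpad) * otf, s=vpad.shape)
    crop = tuple(slice(p, p + s) for p, s in zip(pad, vol.shape))
    return np.clip(out[crop], 0.0, None)
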