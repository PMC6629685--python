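"""Synthetic phantoms and simulated fluorescence acquisitions.

Every downstream measurement in the package can be exercised without
real microscope data: a ground-truth phantom (filaments or point
emitters) is blurred with a known Gaussian PSF, scaled to a photon
budget and corrupted with Poisson counting noise.  Two realizations of
the same field with independent noise provide exactly the input FRC
needs; the photon-limited noise model is pure Poisson (no read noise),
the simplest model consistent with fluorescence counting statistics.

Defaults emulate a confocal acquisition: 50 nm pixels, 250 nm lateral
FWHM, 200 peak photons; in 3D the axial FWHM defaults to three times
the lateral one, matching the anisotropy typical of single-objective
microscopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image import ImageData

__all__ = ["AcquisitionSpec", "make_phantom", "simulate_acquisition", "simulate_pair"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class AcquisitionSpec:
    """Parameters of a simulated acquisition.

    ``psf_fwhm_nm`` may be a scalar (isotropic) or per-axis tuple; for
    3D scalars the axial FWHM is set to ``axial_factor`` times lateral.
    """

    kind: str = "filaments"  # filaments | points | mixed
    shape: tuple[int, ...] = (256, 256)
    pixel_size_nm: float = 50.0
    psf_fwhm_nm: float | tuple[float, ...] = 250.0
    peak_photons: float = 200.0
    background_photons: float = 0.0
    n_realizations: int = 2
    seed: int = 0
    axial_factor: float = 3.0
    n_filaments: int | None = None
    point_density: float = 2e-4  # emitters per pixel

    def fwhm_per_axis(self) -> tuple[float, ...]:
        ndim = len(self.shape)
        if np.isscalar(self.psf_fwhm_nm):
            lateral = float(self.psf_fwhm_nm)
            if ndim == 3:
                return (self.axial_factor * lateral, lateral, lateral)
            return (lateral,) * ndim
        fwhm = tuple(float(f) for f in self.psf_fwhm_nm)
        if len(fwhm) != ndim:
            raise ValueError("psf_fwhm_nm rank does not match shape")
        return fwhm

    def __post_init__(self) -> None:
        if self.peak_photons <= 0:
            raise ValueError("peak_photons must be positive")
        if min(self.shape) < 2:
            raise ValueError("degenerate shape")


def _render_points(rng: np.random.Generator, shape, density: float) -> np.ndarray:
    """Isolated emitters deposited with sub-pixel bilinear weights."""
    img = np.zeros(shape, dtype=float)
    n = rng.poisson(density * np.prod(shape))
    coords = rng.uniform(0, 1, size=(n, len(shape))) * (np.asarray(shape) - 1)
    for c in coords:
        base = np.floor(c).astype(int)
        frac = c - base
        for corner in np.ndindex(*(2,) * len(shape)):
            w = np.prod([f if o else 1 - f for o, f in zip(corner, frac)])
            idx = tuple(np.minimum(base + corner, np.asarray(shape) - 1))
            img[idx] += w
    return img


def _render_filaments(rng: np.random.Generator, shape, n_filaments: int) -> np.ndarray:
    """Smooth random-walk curves splatted with a narrow Gaussian profile."""
    img = np.zeros(shape, dtype=float)
    ndim = len(shape)
    extent = np.asarray(shape, dtype=float)
    n_steps = int(2.5 * max(shape))
    for _ in range(n_filaments):
        pos = rng.uniform(0.1, 0.9, size=ndim) * extent
        direction = rng.normal(size=ndim)
        direction /= np.linalg.norm(direction)
        for _ in range(n_steps):
            # curvature: small random rotation of the heading
            direction += 0.15 * rng.normal(size=ndim)
            direction /= np.linalg.norm(direction)
            pos = pos + direction
            # reflect at the borders
            for a in range(ndim):
                if pos[a] < 1 or pos[a] > extent[a] - 2:
                    direction[a] *= -1
                    pos[a] = np.clip(pos[a], 1, extent[a] - 2)
            base = np.floor(pos).astype(int)
            frac = pos - base
            for corner in np.ndindex(*(2,) * ndim):
                w = np.prod([f if o else 1 - f for o, f in zip(corner, frac)])
                img[tuple(base + corner)] += w
    return img


def make_phantom(spec: AcquisitionSpec) -> ImageData:
    """Noiseless, unblurred ground-truth phantom with values in [0, 1].

    Deterministic given ``spec.seed``; the acquisition noise streams are
    drawn from separate seeds so phantom and noise are independent.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    if spec.kind == "points":
        img = _render_points(rng, shape, spec.point_density)
    elif spec.kind == "filaments":
        n_fil = spec.n_filaments
        if n_fil is None:
            n_fil = max(3, int(round(max(shape) / 32)))
        img = _render_filaments(rng, shape, n_fil)
    elif spec.kind == "mixed":
        n_fil = spec.n_filaments or max(2, int(round(max(shape) / 64)))
        img = _render_filaments(rng, shape, n_fil)
        img += _render_points(rng, shape, spec.point_density)
    else:
        raise ValueError(f"unknown phantom kind {spec.kind!r}")
    peak = img.max()
    if peak > 0:
        img = np.clip(img / peak, 0.0, 1.0)
    return ImageData(img, (spec.pixel_size_nm,) * len(shape))


def blur_phantom(phantom: ImageData, spec: AcquisitionSpec) -> ImageData:
    """Gaussian-blur the phantom with the spec's PSF, renormalized to peak 1."""
    sigma_px = [
        f * _FWHM_TO_SIGMA / s for f, s in zip(spec.fwhm_per_axis(), phantom.spacing)
    ]
    blurred = ndimage.gaussian_filter(phantom.pixels, sigma_px, mode="reflect")
    peak = blurred.max()
    if peak > 0:
        blurred = blurred / peak
    return phantom.with_pixels(blurred)


def simulate_acquisition(
    phantom: ImageData, spec: AcquisitionSpec
) -> list[ImageData]:
    """Simulate Poisson-noise realizations of the blurred phantom.

    Each realization is Poisson(peak_photons * blurred + background);
    the noiseless signal is identical across realizations and the noise
    streams are independent, derived from ``spec.seed``.
    """
    blurred = blur_phantom(phantom, spec)
    expected = spec.peak_photons * blurred.pixels + spec.background_photons
    out = []
    for i in range(spec.n_realizations):
        rng = np.random.default_rng((int(spec.seed), 1_000_003 + i))
        out.append(phantom.with_pixels(rng.poisson(expected).astype(float)))
    return out


def simulate_pair(spec: AcquisitionSpec) -> tuple[ImageData, list[ImageData]]:
    """Phantom plus its noise realizations in one call."""
    spec = replace(spec, n_realizations=max(2, spec.n_realizations))
    phantom = make_phantom(spec)
    return phantom, simulate_acquisition(phantom, spec)
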