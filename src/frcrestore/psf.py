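"""Gaussian PSF models derived from FRC/SFSC resolution estimates.

The blind-restoration premise: treat the measured resolution ``d_min``
as the FWHM of an effective Gaussian PSF, FWHM = 2 sqrt(2 ln 2) sigma.
In 3D, separate lateral and axial FWHM values (e.g. from sectioned FSC
at 0 and 90 degrees) give an anisotropic separable kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import ImageData, read_image, write_image

__all__ = ["PSFModel", "resolution_to_sigma", "sigma_to_fwhm", "make_gaussian_psf"]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


def resolution_to_sigma(d_min: float) -> float:
    """Gaussian sigma whose FWHM equals the resolution value (nm)."""
    if d_min <= 0:
        raise ValueError("resolution must be positive")
    return d_min / FWHM_FACTOR


def sigma_to_fwhm(sigma: float) -> float:
    return sigma * FWHM_FACTOR


@dataclass
class PSFModel:
    """A rendered, unit-sum separable Gaussian kernel with its parameters."""

    fwhm_nm: tuple[float, ...]
    sigma_nm: tuple[float, ...]
    kernel: np.ndarray
    spacing_nm: tuple[float, ...]

    @property
    def ndim(self) -> int:
        return self.kernel.ndim

    def to_tiff(self, path) -> None:
        write_image(ImageData(self.kernel, self.spacing_nm), path)

    @classmethod
    def from_tiff(cls, path, spacing=None) -> "PSFModel":
        img = read_image(path, spacing=spacing)
        kernel = np.asarray(img.pixels, dtype=float)
        kernel = kernel / kernel.sum()
        # FWHM recovered from the second moment of the stored kernel
        sigmas = []
        for axis in range(kernel.ndim):
            coords = (np.arange(kernel.shape[axis]) - kernel.shape[axis] // 2)
            marg = kernel.sum(axis=tuple(a for a in range(kernel.ndim) if a != axis))
            sigmas.append(np.sqrt((marg * coords**2).sum()) * img.spacing[axis])
        fwhm = tuple(sigma_to_fwhm(s) for s in sigmas)
        return cls(fwhm, tuple(sigmas), kernel, img.spacing)


def make_gaussian_psf(
    fwhm: float | tuple[float, ...],
    spacing: float | tuple[float, ...],
    shape: tuple[int, ...] | None = None,
    ndim: int | None = None,
) -> PSFModel:
    """Render a normalized separable Gaussian PSF.

    ``fwhm`` and ``spacing`` are per-axis in nm (scalars broadcast).
    Kernel sizes are forced odd so the maximum sits on a voxel centre;
    the automatic support covers +-4 sigma per axis.
    """
    fwhm_t = tuple(np.atleast_1d(np.asarray(fwhm, dtype=float)))
    spacing_t = tuple(np.atleast_1d(np.asarray(spacing, dtype=float)))
    if ndim is None:
        if shape is not None:
            ndim = len(shape)
        else:
            ndim = max(len(fwhm_t), len(spacing_t))
            if ndim == 1:
                ndim = 2  # scalars mean an isotropic 2D kernel

    if len(fwhm_t) == 1:
        fwhm_t = fwhm_t * ndim
    if len(spacing_t) == 1:
        spacing_t = spacing_t * ndim
    if len(fwhm_t) != len(spacing_t):
        raise ValueError("fwhm and spacing ranks differ")
    if any(f <= 0 for f in fwhm_t) or any(s <= 0 for s in spacing_t):
        raise ValueError("fwhm and spacing must be positive")
    sigma_nm = tuple(f / FWHM_FACTOR for f in fwhm_t)
    sigma_px = [s / d for s, d in zip(sigma_nm, spacing_t)]
    if shape is None:
        shape = tuple(2 * int(np.ceil(4.0 * s)) + 1 for s in sigma_px)
    else:
        shape = tuple(n if n % 2 else n + 1 for n in shape)
    profiles = []
    for n, s in zip(shape, sigma_px):
        x = np.arange(n) - n // 2
        profiles.append(np.exp(-(x**2) / (2.0 * s**2)))
    kernel = profiles[0]
    for p in profiles[1:]:
        kernel = np.multiply.outer(kernel, p)
    kernel /= kernel.sum()
    return PSFModel(fwhm_t, sigma_nm, kernel, spacing_t)
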