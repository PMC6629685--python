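"""Image container, TIFF I/O and spatial preprocessing.

All physical lengths are stored in nanometres.  Axis order is ``(y, x)``
for 2D images and ``(z, y, x)`` for volumes, with ``z`` the optical axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "ImageData",
    "read_image",
    "write_image",
    "resample_isotropic",
    "apply_window",
    "register_translation",
]

_DEFAULT_AXES = {2: ("y", "x"), 3: ("z", "y", "x")}


@dataclass
class ImageData:
    """A 2D or 3D pixel array with per-axis physical spacing.

    Parameters
    ----------
    pixels
        Non-negative real array, ``(y, x)`` or ``(z, y, x)``.
    spacing
        Per-axis sample spacing in nm, one entry per array axis.
    axes
        Axis labels; defaults to ``('y', 'x')`` / ``('z', 'y', 'x')``.
    """

    pixels: np.ndarray
    spacing: tuple[float, ...]
    axes: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"expected a 2D or 3D array, got {self.pixels.ndim}D")
        self.spacing = tuple(float(s) for s in np.atleast_1d(self.spacing))
        if len(self.spacing) == 1:
            self.spacing = self.spacing * self.pixels.ndim
        if len(self.spacing) != self.pixels.ndim:
            raise ValueError(
                f"{len(self.spacing)} spacing entries for a {self.pixels.ndim}D array"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")
        if self.axes is None:
            self.axes = _DEFAULT_AXES[self.pixels.ndim]
        else:
            self.axes = tuple(self.axes)
            if len(self.axes) != self.pixels.ndim:
                raise ValueError("number of axis labels must equal array rank")

    @property
    def ndim(self) -> int:
        return self.pixels.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "ImageData":
        """Same geometry, new pixel values."""
        return ImageData(pixels, self.spacing, self.axes)

    def astype(self, dtype) -> "ImageData":
        return self.with_pixels(self.pixels.astype(dtype))


def _spacing_from_tiff(tif: tifffile.TiffFile) -> tuple[float, ...] | None:
    """Extract nm spacing from TIFF resolution tags / ImageJ metadata."""
    page = tif.pages[0]
    tags = page.tags
    try:
        unit = tags["ResolutionUnit"].value
        xres = tags["XResolution"].value
        yres = tags["YResolution"].value
    except KeyError:
        return None
    # resolution stored as (numerator, denominator) pixels per unit
    def _per_px(res):
        num, den = res
        if num == 0:
            return None
        return den / num  # length units per pixel

    dx, dy = _per_px(xres), _per_px(yres)
    if dx is None or dy is None:
        return None
    ij = tif.imagej_metadata or {}
    scale = {2: 2.54e7, 3: 1e7}.get(int(unit))  # inch / cm -> nm
    if scale is None:
        # RESUNIT.NONE: only trust it when an ImageJ unit is declared
        ij_unit = ij.get("unit")
        if ij_unit is None:
            return None
        scale = {"nm": 1.0, "um": 1e3, "micron": 1e3, "µm": 1e3}.get(ij_unit)
        if scale is None:
            return None
    dy_nm, dx_nm = dy * scale, dx * scale
    if tif.series[0].ndim == 3:
        dz = ij.get("spacing")
        if dz is None:
            return None
        zunit = ij.get("unit", "nm")
        zscale = {"nm": 1.0, "um": 1e3, "micron": 1e3, "µm": 1e3}.get(zunit, 1.0)
        return (float(dz) * zscale, dy_nm, dx_nm)
    return (dy_nm, dx_nm)


def read_image(path, spacing: tuple[float, ...] | float | None = None) -> ImageData:
    """Read a single- or multi-page TIFF as :class:`ImageData`.

    ``spacing`` (nm) overrides any metadata; if the file carries no
    resolution metadata and no override is given an error is raised —
    a pixel size is never silently assumed.
    """
    with tifffile.TiffFile(str(path)) as tif:
        pixels = tif.asarray()
        meta_spacing = _spacing_from_tiff(tif)
    if spacing is not None:
        spc = tuple(np.atleast_1d(np.asarray(spacing, dtype=float)))
        if len(spc) == 1:
            spc = spc * pixels.ndim
    elif meta_spacing is not None:
        spc = meta_spacing
    else:
        raise ValueError(
            f"{path}: no pixel-size metadata found; pass spacing= explicitly "
            "(unknown pixel size is never assumed to be 1)"
        )
    return ImageData(pixels, spc)


def write_image(image: ImageData, path) -> None:
    """Write a TIFF (multi-page for 3D) with nm spacing metadata.

    Integer data round-trips bit-exactly; floats are stored as float32
    unless already float64.
    """
    pixels = image.pixels
    if pixels.dtype.kind == "f" and pixels.dtype.itemsize > 4:
        pixels = pixels.astype(np.float32)
    # resolution tags: pixels per nm, unit NONE (nm is not a TIFF unit)
    dy, dx = image.spacing[-2], image.spacing[-1]
    meta = {"axes": "".join(a.upper() for a in image.axes), "unit": "nm"}
    if image.ndim == 3:
        meta["spacing"] = image.spacing[0]
    tifffile.imwrite(
        str(path),
        pixels,
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata=meta,
    )


def resample_isotropic(image: ImageData, order: int = 1) -> ImageData:
    """Linearly resample a volume so all axes share the finest spacing.

    Axes already at the minimum spacing are untouched; coarser axes are
    upsampled.  2D images are returned unchanged with a warning.
    """
    if image.ndim == 2:
        warnings.warn("resample_isotropic is a no-op on 2D images", stacklevel=2)
        return image
    target = min(image.spacing)
    factors = tuple(s / target for s in image.spacing)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return image
    resampled = ndimage.zoom(
        np.asarray(image.pixels, dtype=float), factors, order=order, mode="nearest"
    )
    return ImageData(resampled, (target,) * image.ndim, image.axes)


_WINDOWS = {"hamming": np.hamming, "hann": np.hanning, "blackman": np.blackman}


def apply_window(image: ImageData, kind: str = "hamming") -> ImageData:
    """Multiply by a separable apodization window to suppress edge effects.

    Hamming is the standard 2D FRC preprocessing; Hann and Blackman
    trade a wider main lobe for much faster sidelobe decay, which
    matters for 3D sectioned measurements where sidelobe leakage of the
    dominant lateral spectrum can masquerade as axial correlation.
    """
    try:
        fn = _WINDOWS[kind]
    except KeyError:
        raise ValueError(
            f"unknown window kind {kind!r}; supported: {sorted(_WINDOWS)}"
        ) from None
    out = np.asarray(image.pixels, dtype=float).copy()
    for axis, n in enumerate(image.shape):
        w = fn(n)
        out *= w.reshape([-1 if a == axis else 1 for a in range(image.ndim)])
    return image.with_pixels(out)


def register_translation(
    reference: ImageData, moving: ImageData, upsample_factor: int = 10
) -> tuple[np.ndarray, ImageData]:
    """Phase-correlation translation registration.

    Returns the detected shift (pixels, subpixel-refined) and the moving
    image resampled onto the reference grid by linear interpolation.
    Integer accuracy is guaranteed; subpixel refinement is best effort.
    """
    if reference.shape != moving.shape:
        raise ValueError(
            f"shape mismatch: {reference.shape} vs {moving.shape}"
        )
    correction, _, _ = phase_cross_correlation(
        np.asarray(reference.pixels, dtype=float),
        np.asarray(moving.pixels, dtype=float),
        upsample_factor=upsample_factor,
        normalization=None,
    )
    correction = np.asarray(correction, dtype=float)
    # report the displacement of `moving` relative to `reference`
    shift = -correction
    if np.allclose(correction, np.round(correction)):
        registered = np.roll(
            moving.pixels, tuple(int(s) for s in np.round(correction)),
            axis=tuple(range(moving.ndim)),
        )
    else:
        registered = ndimage.shift(
            np.asarray(moving.pixels, dtype=float), correction, order=1,
            mode="grid-wrap",
        )
    return shift, moving.with_pixels(registered)
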