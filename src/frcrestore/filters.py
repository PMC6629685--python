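"""Frequency-domain low-pass denoising with an FRC-derived cutoff.

Three classic transfer functions are provided, all parameterized by the
cutoff frequency ``r_th`` (1/nm), normally the inverse of the FRC
resolution: the ideal filter clips everything beyond the cutoff, the
Butterworth filter of order n transitions smoothly (H = 0.5 at the
cutoff) and the Gaussian filter rolls off slowly (H = exp(-1/2) = 0.607
at the cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import ImageData

__all__ = ["TransferFunction", "transfer_value", "lowpass_transfer",
           "frequency_grid", "filter_image"]


def transfer_value(kind: str, r, r_th: float, n: int | None = None):
    """Analytic low-pass transfer H(r) for cutoff ``r_th``.

    ideal:       1 for r < r_th, else 0
    butterworth: 1 / (1 + (r / r_th)^(2n))
    gaussian:    exp(-r^2 / (2 r_th^2))
    """
    if r_th <= 0:
        raise ValueError("cutoff r_th must be positive")
    r = np.asarray(r, dtype=float)
    if kind == "ideal":
        return (r < r_th).astype(float)
    if kind == "butterworth":
        if n is None or n < 1:
            raise ValueError("butterworth filter needs order n >= 1")
        return 1.0 / (1.0 + (r / r_th) ** (2 * int(n)))
    if kind == "gaussian":
        return np.exp(-(r**2) / (2.0 * r_th**2))
    raise ValueError(f"unknown filter kind {kind!r}")


def frequency_grid(shape: tuple[int, ...], spacing_nm: tuple[float, ...]) -> np.ndarray:
    """Radial spatial-frequency grid in 1/nm, FFT sample layout."""
    axes = [np.fft.fftfreq(n, d=s) for n, s in zip(shape, spacing_nm)]
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    return np.sqrt(sum(g**2 for g in grids))


@dataclass
class TransferFunction:
    """A sampled low-pass transfer function on an image's frequency grid."""

    kind: str
    r_th: float  # 1/nm
    values: np.ndarray  # H on the FFT grid (unshifted layout)
    order: int | None = None

    @classmethod
    def for_image(cls, image: ImageData, kind: str, r_th: float,
                  order: int | None = None) -> "TransferFunction":
        grid = frequency_grid(image.shape, image.spacing)
        return cls(kind, float(r_th), transfer_value(kind, grid, r_th, order), order)


def lowpass_transfer(
    kind: str,
    r_th: float,
    n: int | None = None,
    grid: np.ndarray | None = None,
    image: ImageData | None = None,
) -> TransferFunction:
    """Sample a low-pass transfer function on a frequency grid (1/nm).

    Either an explicit radial ``grid`` or an ``image`` (whose grid is
    derived from shape and spacing) must be given.
    """
    if grid is None:
        if image is None:
            raise ValueError("provide either grid or image")
        grid = frequency_grid(image.shape, image.spacing)
    return TransferFunction(kind, float(r_th), transfer_value(kind, grid, r_th, n), n)


def filter_image(image: ImageData, transfer: TransferFunction) -> ImageData:
    """Apply a sampled transfer function in the frequency domain."""
    if transfer.values.shape != image.shape:
        raise ValueError(
            f"transfer sampled on {transfer.values.shape}, image is {image.shape}"
        )
    spectrum = np.fft.fftn(np.asarray(image.pixels, dtype=float))
    out = np.fft.ifftn(spectrum * transfer.values)
    return image.with_pixels(out.real)
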