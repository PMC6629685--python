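"""Fourier ring correlation: two-image, one-image and threshold criteria.

FRC measures the spectral signal-to-noise of an image pair sharing the
same structure but independent noise.  Per concentric frequency ring
``r_i`` the normalized cross-correlation is

    FRC(r_i) = Re( sum F1 . conj(F2) ) / sqrt( sum|F1|^2 . sum|F2|^2 )

and the resolution ``d_min`` is the inverse of the first frequency at
which the curve drops below a threshold (fixed 1/7 by default).

A single image can be measured by checkerboard sub-sampling into two
statistically independent sub-image pairs; the resulting raw resolution
is biased by the doubled pixel pitch and the sub-sampling modulation, so
it is corrected with a monotone calibration fitted against the two-image
reference at the same threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import ImageData

__all__ = [
    "FRCCurve",
    "ThresholdCurve",
    "ResolutionResult",
    "CalibrationModel",
    "frc_curve",
    "checkerboard_split",
    "one_image_frc",
    "make_threshold",
    "resolution_from_curve",
    "fit_calibration",
]


@dataclass
class FRCCurve:
    """Binned spectral correlation over spatial frequency.

    ``bin_center_freq`` is in cycles/pixel; divide by ``pixel_size_nm``
    for physical frequency in 1/nm.
    """

    bin_center_freq: np.ndarray
    correlation: np.ndarray
    n_points: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.bin_center_freq = np.asarray(self.bin_center_freq, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        self.n_points = np.asarray(self.n_points, dtype=int)

    @property
    def freq_nm_inv(self) -> np.ndarray:
        """Physical spatial frequency per bin, 1/nm."""
        return self.bin_center_freq / self.pixel_size_nm


@dataclass
class ThresholdCurve:
    bin_center_freq: np.ndarray
    threshold: np.ndarray
    criterion: str  # "fixed_1_7" | "snr_e"
    snr_e: float | None = None


@dataclass
class ResolutionResult:
    """Numeric resolution extracted from an FRC/FSC curve."""

    d_min_nm: float
    crossing_freq: float  # 1/nm
    criterion: str
    calibrated: bool = False
    mode: str = "two_image"
    no_crossing: bool = False


@dataclass
class CalibrationModel:
    """Monotone polynomial mapping raw one-image d_min to the two-image
    reference, valid only for the threshold it was fitted at."""

    coefficients: np.ndarray  # numpy polynomial (highest degree first)
    threshold: str = "fixed_1_7"
    fit_range_nm: tuple[float, float] = (0.0, np.inf)

    def apply(self, d_min_nm: float) -> float:
        return float(np.polyval(self.coefficients, d_min_nm))


# ---------------------------------------------------------------------------
# ring binning

def _ring_indices(shape: tuple[int, ...], bin_width: float) -> tuple[np.ndarray, np.ndarray]:
    """Ring (shell) index per Fourier sample plus bin centre frequencies.

    Frequencies are in cycles/pixel; rings are one index-rounding wide.
    """
    grids = np.meshgrid(*[np.fft.fftfreq(n) for n in shape], indexing="ij", sparse=True)
    r = np.sqrt(sum(g**2 for g in grids))
    idx = np.rint(r / bin_width).astype(int)
    centers = np.arange(idx.max() + 1) * bin_width
    return idx, centers


def _binned_correlation(
    f1: np.ndarray,
    f2: np.ndarray,
    idx: np.ndarray,
    centers: np.ndarray,
    max_freq: float = 0.5,
):
    """Per-ring Eq.-style normalized cross correlation via bincount."""
    flat = idx.ravel()
    nbins = len(centers)
    cross = np.bincount(flat, weights=(f1 * np.conj(f2)).real.ravel(), minlength=nbins)
    p1 = np.bincount(flat, weights=np.abs(f1).ravel() ** 2, minlength=nbins)
    p2 = np.bincount(flat, weights=np.abs(f2).ravel() ** 2, minlength=nbins)
    n = np.bincount(flat, minlength=nbins)
    keep = (n > 0) & (p1 > 0) & (p2 > 0) & (centers <= max_freq + 1e-12)
    corr = cross[keep] / np.sqrt(p1[keep] * p2[keep])
    return centers[keep], corr, n[keep]


def frc_curve(
    image1: ImageData,
    image2: ImageData,
    bin_width: float | None = None,
    max_freq: float = 0.5,
) -> FRCCurve:
    """Two-image FRC (2D) / FSC (3D) curve.

    The caller is expected to have windowed and registered the images;
    the workflow wrappers apply a Hamming window first.  Rings are
    defined on the centered spectrum with default width one frequency
    pixel; empty or zero-power bins are dropped.
    """
    if image1.shape != image2.shape:
        raise ValueError(f"shape mismatch: {image1.shape} vs {image2.shape}")
    if bin_width is None:
        bin_width = 1.0 / max(image1.shape)
    f1 = np.fft.fftn(np.asarray(image1.pixels, dtype=float))
    f2 = np.fft.fftn(np.asarray(image2.pixels, dtype=float))
    idx, centers = _ring_indices(image1.shape, bin_width)
    freq, corr, n = _binned_correlation(f1, f2, idx, centers, max_freq)
    return FRCCurve(freq, corr, n, pixel_size_nm=float(image1.spacing[-1]))


# ---------------------------------------------------------------------------
# one-image FRC

def checkerboard_split(image: ImageData) -> tuple[tuple[ImageData, ImageData], tuple[ImageData, ImageData]]:
    """Split one image into two statistically independent sub-image pairs.

    Pair A = ((even, even), (odd, odd)), pair B = ((even, odd),
    (odd, even)) pixel parity classes.  Odd trailing rows/columns are
    truncated so every class has identical floor-half dimensions; the
    sub-image pixel pitch is twice the original.
    """
    if image.ndim != 2:
        raise ValueError("checkerboard_split expects a 2D image")
    px = image.pixels
    ny, nx = (s - s % 2 for s in px.shape)
    px = px[:ny, :nx]
    spacing = tuple(2 * s for s in image.spacing)
    sub = lambda py, pxx: ImageData(px[py::2, pxx::2], spacing, image.axes)
    pair_a = (sub(0, 0), sub(1, 1))
    pair_b = (sub(0, 1), sub(1, 0))
    return pair_a, pair_b


def one_image_frc(
    image: ImageData,
    calibration: CalibrationModel | None = None,
    bin_width: float | None = None,
    window: bool = True,
    threshold: str = "fixed_1_7",
    snr_e: float | None = None,
) -> tuple[FRCCurve, ResolutionResult]:
    """FRC from a single image via checkerboard sub-sampling.

    The curves of the two diagonal sub-image pairs are averaged bin-wise
    (averaging suppresses spectral-domain symmetries that appear with
    strongly oriented structures).  The frequency axis is reported
    against the ORIGINAL pixel size, so the raw curve appears shifted
    towards higher frequencies; a supplied calibration corrects the
    extracted ``d_min`` (and thereby the pixel-pitch difference).
    """
    if image.ndim != 2:
        raise ValueError("one_image_frc expects a 2D image")
    if min(image.shape) < 16:
        raise ValueError("image too small for one-image FRC (need >= 16x16)")
    from .image import apply_window

    pair_a, pair_b = checkerboard_split(image)
    curves = []
    for a, b in (pair_a, pair_b):
        if window:
            a, b = apply_window(a), apply_window(b)
        curves.append(frc_curve(a, b, bin_width=bin_width))
    ca, cb = curves
    nbins = min(len(ca.correlation), len(cb.correlation))
    corr = 0.5 * (ca.correlation[:nbins] + cb.correlation[:nbins])
    # attach the ORIGINAL pixel size to the sub-image frequency axis
    curve = FRCCurve(
        ca.bin_center_freq[:nbins],
        corr,
        ca.n_points[:nbins] + cb.n_points[:nbins],
        pixel_size_nm=float(image.spacing[-1]),
    )
    thr = make_threshold(threshold, curve, snr_e=snr_e)
    result = resolution_from_curve(curve, thr)
    result.mode = "one_image"
    if calibration is not None:
        if calibration.threshold != threshold:
            raise ValueError(
                f"calibration fitted for {calibration.threshold!r}, "
                f"requested {threshold!r}"
            )
        if not result.no_crossing:
            result.d_min_nm = calibration.apply(result.d_min_nm)
            result.crossing_freq = 1.0 / result.d_min_nm
            result.calibrated = True
    return curve, result


# ---------------------------------------------------------------------------
# thresholds and resolution extraction

def snr_threshold(snr_e: float, n_points: np.ndarray) -> np.ndarray:
    """SNR-based per-ring threshold curve.

    T(r_i) = (SNR_e + (2 sqrt(SNR_e) + 1)/sqrt(N)) /
             (SNR_e + 1 + 2 sqrt(SNR_e)/sqrt(N))

    with N the number of Fourier samples in the ring.  SNR_e = 0.5 is
    the one-bit criterion; as N -> inf, T -> SNR_e / (SNR_e + 1).
    """
    n = np.asarray(n_points, dtype=float)
    s = np.sqrt(snr_e)
    return (snr_e + (2 * s + 1) / np.sqrt(n)) / (snr_e + 1 + 2 * s / np.sqrt(n))


def make_threshold(
    criterion: str, curve: FRCCurve, snr_e: float | None = None
) -> ThresholdCurve:
    """Threshold curve on the same binning as ``curve``."""
    if criterion == "fixed_1_7":
        thr = np.full_like(curve.correlation, 1.0 / 7.0)
        return ThresholdCurve(curve.bin_center_freq, thr, criterion)
    if criterion == "snr_e":
        if snr_e is None or snr_e < 0:
            raise ValueError("snr_e criterion requires snr_e >= 0")
        thr = snr_threshold(snr_e, curve.n_points)
        return ThresholdCurve(curve.bin_center_freq, thr, criterion, snr_e=snr_e)
    raise ValueError(f"unknown threshold criterion {criterion!r}")


def resolution_from_curve(curve: FRCCurve, threshold: ThresholdCurve) -> ResolutionResult:
    """First (lowest-frequency) threshold crossing, linearly interpolated.

    The DC bin is never eligible.  If the curve never drops below the
    threshold, the result is flagged ``no_crossing`` and the sampling
    bound 2 * pixel size is reported.
    """
    if len(curve.correlation) != len(threshold.threshold):
        raise ValueError("curve and threshold have different binnings")
    diff = curve.correlation - threshold.threshold
    below = np.where(diff[1:] < 0)[0] + 1  # skip DC bin
    if len(below) == 0:
        return ResolutionResult(
            d_min_nm=2.0 * curve.pixel_size_nm,
            crossing_freq=1.0 / (2.0 * curve.pixel_size_nm),
            criterion=threshold.criterion,
            no_crossing=True,
        )
    j = below[0]
    f = curve.bin_center_freq
    if j == 0 or diff[j - 1] <= 0:
        f_cross = f[j]
    else:
        frac = diff[j - 1] / (diff[j - 1] - diff[j])
        f_cross = f[j - 1] + frac * (f[j] - f[j - 1])
    freq_nm = f_cross / curve.pixel_size_nm
    return ResolutionResult(
        d_min_nm=1.0 / freq_nm,
        crossing_freq=freq_nm,
        criterion=threshold.criterion,
    )


# ---------------------------------------------------------------------------
# one-image calibration

def fit_calibration(
    pairs, degree: int = 2, threshold: str = "fixed_1_7"
) -> CalibrationModel:
    """Least-squares monotone polynomial mapping raw one-image d_min to
    the two-image reference.

    Fitted at the stated degree (default quadratic); if the fit is not
    monotone increasing over the data range it is refit linearly.  At
    least four pairs spanning a resolution range are required.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 4:
        raise ValueError("need >= 4 (raw, reference) pairs")
    raw, ref = pairs[:, 0], pairs[:, 1]
    lo, hi = float(raw.min()), float(raw.max())
    for deg in (degree, 1):
        coef = np.polyfit(raw, ref, deg)
        deriv = np.polyder(coef)
        grid = np.linspace(lo, hi, 256)
        if np.all(np.polyval(deriv, grid) >= 0) or deg == 1:
            break
    return CalibrationModel(coef, threshold=threshold, fit_range_nm=(lo, hi))
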