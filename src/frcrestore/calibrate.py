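"""Build the one-image FRC calibration from a simulated acquisition series.

The raw one-image resolution is biased (the checkerboard sub-images have
twice the pixel pitch and the diagonal sub-sampling modulates the
spectrum), so it is calibrated against the two-image reference.  The
procedure mirrors how one would calibrate on a microscope: image a
nearly fixed-resolution scene at a series of sampling densities, measure
raw one-image and reference two-image d_min for each, and fit a monotone
correction.  Here the scenes are simulated filament phantoms imaged at
pixel sizes spanning 29-113 nm with a 250 nm FWHM PSF.
"""

from __future__ import annotations

import numpy as np

from .frc import CalibrationModel, fit_calibration, frc_curve, make_threshold, one_image_frc, resolution_from_curve
from .image import apply_window
from .synthetic import AcquisitionSpec, simulate_pair

__all__ = ["calibration_series", "default_calibration", "DEFAULT_PIXEL_SIZES"]

DEFAULT_PIXEL_SIZES = (29.0, 40.0, 55.0, 70.0, 90.0, 113.0)


def calibration_series(
    pixel_sizes=DEFAULT_PIXEL_SIZES,
    psf_fwhm_nm: float = 250.0,
    peak_photons: float = 200.0,
    shape=(256, 256),
    n_scenes: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """(raw one-image d_min, reference two-image d_min) pairs, in nm."""
    pairs = []
    for i, px in enumerate(pixel_sizes):
        for s in range(n_scenes):
            spec = AcquisitionSpec(
                shape=tuple(shape),
                pixel_size_nm=float(px),
                psf_fwhm_nm=psf_fwhm_nm,
                peak_photons=peak_photons,
                seed=(int(seed) * 1009 + 31 * i + s) % (2**31),
            )
            _, (a, b) = simulate_pair(spec)
            curve = frc_curve(apply_window(a), apply_window(b))
            ref = resolution_from_curve(curve, make_threshold("fixed_1_7", curve))
            _, raw = one_image_frc(a)
            if ref.no_crossing or raw.no_crossing:
                continue
            pairs.append((raw.d_min_nm, ref.d_min_nm))
    return np.asarray(pairs)


def default_calibration(seed: int = 0) -> CalibrationModel:
    """The package's stock calibration, fitted on the synthetic series."""
    return fit_calibration(calibration_series(seed=seed))
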