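"""End-to-end blind restoration pipelines.

Each pipeline measures the effective resolution of the input image,
restores it without any prior knowledge of the optics, and reports the
input/output resolution measured with the same FRC mode:

* ``frc_denoise`` — one-image FRC cutoff + frequency-domain low-pass,
* ``blind_wiener`` — FRC/SFSC-derived Gaussian PSF + Wiener filtering,
* ``blind_rl``    — the same PSF + Richardson-Lucy with FRC stopping.

All pipelines are deterministic given the input image and parameters;
randomness lives exclusively in the synthetic module.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .deconv import DeconvTrace, RLOptions, estimate_snr, rl_deconvolve, wiener_deconvolve
from .filters import TransferFunction, filter_image
from .frc import CalibrationModel, one_image_frc
from .fsc3d import VOLUME_WINDOW, plain_fsc, sfsc, volume_split
from .image import ImageData, apply_window, resample_isotropic
from .psf import make_gaussian_psf

__all__ = ["RestoreReport", "restore", "measure_resolution"]

_METHODS = ("frc_denoise", "blind_wiener", "blind_rl")


@dataclass
class RestoreReport:
    """What was done to an image and what it achieved."""

    method: str
    input_d_min_nm: float
    output_d_min_nm: float
    psf_fwhm_nm: tuple[float, ...] | None
    parameters: dict[str, Any] = field(default_factory=dict)
    trace: Optional[DeconvTrace] = None

    def to_json(self) -> str:
        d = {
            "method": self.method,
            "input_d_min_nm": self.input_d_min_nm,
            "output_d_min_nm": self.output_d_min_nm,
            "psf_fwhm_nm": list(self.psf_fwhm_nm) if self.psf_fwhm_nm else None,
            "parameters": self.parameters,
            "trace": dataclasses.asdict(self.trace) if self.trace else None,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RestoreReport":
        d = json.loads(text)
        trace = DeconvTrace(**d["trace"]) if d.get("trace") else None
        return cls(
            d["method"],
            d["input_d_min_nm"],
            d["output_d_min_nm"],
            tuple(d["psf_fwhm_nm"]) if d.get("psf_fwhm_nm") else None,
            d.get("parameters", {}),
            trace,
        )


def measure_resolution(
    image: ImageData, calibration: CalibrationModel | None = None
) -> float:
    """Single-image resolution: one-image FRC in 2D, split-volume FSC in 3D."""
    if image.ndim == 2:
        _, res = one_image_frc(image, calibration=calibration)
        return res.d_min_nm
    a, b = volume_split(image)
    _, res = plain_fsc(apply_window(a, VOLUME_WINDOW), apply_window(b, VOLUME_WINDOW))
    return res.d_min_nm


def _psf_axes_from_image(image: ImageData, calibration, alpha=np.deg2rad(15.0)):
    """Per-axis Gaussian FWHM estimated blindly from the image itself."""
    if image.ndim == 2:
        _, res = one_image_frc(image, calibration=calibration)
        if res.no_crossing:
            raise ValueError("FRC found no crossing; cannot derive a PSF")
        return (res.d_min_nm,) * 2
    a, b = volume_split(image)
    _, results = sfsc(apply_window(a, VOLUME_WINDOW), apply_window(b, VOLUME_WINDOW), alpha=alpha)
    lateral = results[0].d_min_nm
    axial = max(r.d_min_nm for r in results)
    return (axial, lateral, lateral)


def restore(
    image: ImageData, method: str, **params
) -> tuple[ImageData, RestoreReport]:
    """Run one blind-restoration pipeline.

    Parameters common to all methods: ``calibration`` (one-image FRC
    correction).  Method-specific: ``filter_kind``/``order`` for
    denoising, ``snr_reg`` for Wiener (default: blind Poisson-based
    estimate from the image), ``options`` (:class:`RLOptions`) for RL.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
    calibration = params.pop("calibration", None)
    if image.ndim == 3:
        image = resample_isotropic(image)
    input_d_min = measure_resolution(image, calibration)
    trace = None
    psf_fwhm = None
    if method == "frc_denoise":
        kind = params.pop("filter_kind", "ideal")
        order = params.pop("order", 3)
        cutoff = 1.0 / input_d_min  # 1/nm
        transfer = TransferFunction.for_image(image, kind, cutoff, order)
        restored = filter_image(image, transfer)
        restored = restored.with_pixels(np.clip(restored.pixels, 0.0, None))
        used = {"filter_kind": kind, "cutoff_nm_inv": cutoff}
        if kind == "butterworth":
            used["order"] = order
    elif method == "blind_wiener":
        snr_reg = params.pop("snr_reg", None)
        if snr_reg is None:
            snr_reg = estimate_snr(image)
        psf_fwhm = _psf_axes_from_image(image, calibration)
        psf = make_gaussian_psf(psf_fwhm, image.spacing)
        restored = wiener_deconvolve(image, psf, snr_reg=snr_reg)
        used = {"snr_reg": snr_reg}
    else:  # blind_rl
        options = params.pop("options", None) or RLOptions()
        options.calibration = options.calibration or calibration
        psf_fwhm = _psf_axes_from_image(image, calibration)
        psf = make_gaussian_psf(psf_fwhm, image.spacing)
        restored, trace = rl_deconvolve(image, psf, options)
        used = {
            "max_iter": options.max_iter,
            "stop_grad_threshold": options.stop_grad_threshold,
            "adjustive": options.adjustive,
            "tv_lambda": options.tv_lambda,
            "background": options.background,
        }
    if params:
        raise TypeError(f"unknown parameters for {method}: {sorted(params)}")
    output_d_min = measure_resolution(restored, calibration)
    report = RestoreReport(
        method=method,
        input_d_min_nm=input_d_min,
        output_d_min_nm=output_d_min,
        psf_fwhm_nm=psf_fwhm,
        parameters=used,
        trace=trace,
    )
    return restored, report
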