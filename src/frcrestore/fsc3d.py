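"""3D resolution: Fourier shell correlation and its sectioned variant.

Plain FSC averages over whole spherical shells and therefore hides the
strong lateral/axial resolution anisotropy of single-objective
fluorescence microscopes.  Sectioned FSC (SFSC) divides each shell into
dual wedges — a wedge of angular size alpha plus its point-symmetric
mirror — and rotates the structure in increments of alpha around an
axis in the XY plane, yielding one correlation curve and one resolution
value per orientation.  At alpha = 2*pi the single section contains the
whole sphere and SFSC reduces to plain FSC.

Section membership: each Fourier voxel's frequency vector is projected
onto the plane perpendicular to the rotation axis; the inclination of
that projection with respect to the lateral direction (folded to
[0, pi) by point symmetry) selects the wedge.  Voxels lying exactly on
the rotation axis have undefined inclination and are assigned to the
lateral (theta = 0) section.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frc import FRCCurve, ResolutionResult, _binned_correlation, make_threshold, resolution_from_curve
from .image import ImageData

__all__ = ["SectionedCurves", "volume_split", "sfsc", "plain_fsc", "anisotropy_scale", "pad_to_cube", "VOLUME_WINDOW"]

# apodization used by the 3D measurement workflows: Hann's fast sidelobe
# decay keeps strong lateral power from leaking into the axial sections
VOLUME_WINDOW = "hann"


@dataclass
class SectionedCurves:
    """Per-orientation FSC curves from rotating dual wedges."""

    angles: np.ndarray  # radians, multiples of alpha in [0, pi)
    curves: list[FRCCurve]
    alpha: float
    rotation_axis: str = "y"

    def curve_at(self, theta: float) -> FRCCurve:
        i = int(np.argmin(np.abs(self.angles - theta)))
        return self.curves[i]


def volume_split(volume: ImageData) -> tuple[ImageData, ImageData]:
    """Split one volume into two sub-volumes with independent noise.

    Laterally the (even, even) and (odd, odd) diagonal pixel classes are
    taken per xy-plane (one diagonal only); consecutive z-layers are
    summed pairwise so the volume proportions are maintained without
    introducing axial offsets.  Sub-volume spacing is twice the original
    on every axis.
    """
    if volume.ndim != 3:
        raise ValueError("volume_split expects a 3D volume")
    v = volume.pixels
    nz, ny, nx = (s - s % 2 for s in v.shape)
    v = v[:nz, :ny, :nx]
    spacing = tuple(2 * s for s in volume.spacing)
    a = v[0::2, 0::2, 0::2] + v[1::2, 0::2, 0::2]
    b = v[0::2, 1::2, 1::2] + v[1::2, 1::2, 1::2]
    return (
        ImageData(a, spacing, volume.axes),
        ImageData(b, spacing, volume.axes),
    )


def anisotropy_scale(theta: float, z: float) -> float:
    """Sampling-anisotropy correction factor k(theta) = 1 + (z-1)|sin theta|.

    The voxel size of a section at inclination theta is multiplied by
    k(theta) before frequency bins are converted to physical units; z is
    the axial/lateral sampling ratio (z = 1 means no correction).
    """
    if z < 1:
        raise ValueError("anisotropy factor z must be >= 1")
    return 1.0 + (z - 1.0) * abs(np.sin(theta))


def _section_labels(
    shape: tuple[int, int, int], alpha: float, rotation_axis: str, phi: float
):
    """Wedge index per Fourier voxel plus the section angles.

    A voxel direction is kept only if it lies within ``phi / 2`` of the
    plane perpendicular to the rotation axis (the sector is bounded in
    both angles); its inclination in that plane, folded to [0, pi) by
    point symmetry, selects the wedge.  Excluded voxels get label -1.
    """
    fz, fy, fx = (np.fft.fftfreq(n) for n in shape)
    fz = fz[:, None, None]
    fy = fy[None, :, None]
    fx = fx[None, None, :]
    if rotation_axis == "y":
        a_comp, l_comp, axis_comp = fz, fx, fy
    elif rotation_axis == "x":
        a_comp, l_comp, axis_comp = fz, fy, fx
    else:
        raise ValueError("rotation_axis must be 'y' or 'x' (XY-plane axes)")
    n_sections = max(1, int(round(np.pi / alpha))) if alpha < np.pi else 1
    theta = np.mod(np.arctan2(a_comp, l_comp), np.pi)
    labels = np.mod(np.rint(theta / alpha).astype(int), n_sections)
    labels = np.ascontiguousarray(np.broadcast_to(labels, shape)).copy()
    if n_sections > 1 and phi < np.pi:
        # elevation of the direction out of the rotation plane
        inplane = np.sqrt(a_comp**2 + l_comp**2)
        elev = np.arctan2(np.abs(axis_comp), inplane)
        labels[np.broadcast_to(elev > phi / 2.0, shape)] = -1
        labels.reshape(-1)[0] = 0  # DC stays in the lateral section
    angles = np.arange(n_sections) * alpha
    return labels, angles


def sfsc(
    volume1: ImageData,
    volume2: ImageData,
    alpha: float = np.deg2rad(15.0),
    threshold: str = "snr_e",
    snr_e: float = 0.5,
    anisotropy_z: float = 1.0,
    rotation_axis: str = "y",
    phi: float | None = None,
    bin_width: float | None = None,
    max_freq: float = 0.5,
) -> tuple[SectionedCurves, list[ResolutionResult]]:
    """Sectioned FSC with per-orientation resolution values.

    The volumes are expected to be isotropically resampled and windowed
    by the caller.  ``alpha`` is both the wedge size and the rotation
    increment and must divide pi (alpha >= pi collapses to plain FSC).
    The default threshold is the one-bit criterion (SNR_e = 0.5) using
    each section's own per-shell voxel counts; the frequency axis of the
    section at angle theta is corrected by ``anisotropy_scale`` before
    d_min is reported.
    """
    if volume1.shape != volume2.shape:
        raise ValueError(f"shape mismatch: {volume1.shape} vs {volume2.shape}")
    if volume1.ndim != 3:
        raise ValueError("sfsc expects 3D volumes")
    if alpha < np.pi and abs(np.pi / alpha - round(np.pi / alpha)) > 1e-9:
        raise ValueError("alpha must divide pi (or be >= pi for plain FSC)")
    shape = volume1.shape
    if bin_width is None:
        bin_width = 1.0 / max(shape)
    f1 = np.fft.fftn(np.asarray(volume1.pixels, dtype=float))
    f2 = np.fft.fftn(np.asarray(volume2.pixels, dtype=float))
    from .frc import _ring_indices

    shell_idx, centers = _ring_indices(shape, bin_width)
    if phi is None:
        phi = alpha
    labels, angles = _section_labels(shape, alpha, rotation_axis, phi)
    voxel_nm = float(volume1.spacing[-1])
    curves: list[FRCCurve] = []
    results: list[ResolutionResult] = []
    for s, theta in enumerate(angles):
        mask = labels == s
        freq, corr, n = _binned_correlation(
            f1[mask], f2[mask], shell_idx[mask], centers, max_freq
        )
        k = anisotropy_scale(theta, anisotropy_z)
        curve = FRCCurve(freq, corr, n, pixel_size_nm=voxel_nm * k)
        thr = make_threshold(threshold, curve, snr_e=snr_e)
        res = resolution_from_curve(curve, thr)
        res.mode = "sfsc"
        curves.append(curve)
        results.append(res)
    return SectionedCurves(angles, curves, alpha, rotation_axis), results


def plain_fsc(
    volume1: ImageData,
    volume2: ImageData,
    threshold: str = "snr_e",
    snr_e: float = 0.5,
    bin_width: float | None = None,
) -> tuple[FRCCurve, ResolutionResult]:
    """Whole-shell FSC (the alpha = 2*pi limit of SFSC)."""
    sections, results = sfsc(
        volume1, volume2, alpha=2 * np.pi, threshold=threshold,
        snr_e=snr_e, bin_width=bin_width,
    )
    return sections.curves[0], results[0]


def pad_to_cube(volume: ImageData) -> ImageData:
    """Zero-pad an isotropically sampled volume to a cube."""
    if volume.ndim != 3:
        raise ValueError("pad_to_cube expects a 3D volume")
    n = max(volume.shape)
    pads = []
    for s in volume.shape:
        before = (n - s) // 2
        pads.append((before, n - s - before))
    return volume.with_pixels(np.pad(volume.pixels, pads))
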