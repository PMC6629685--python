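# frcrestore

Blind image restoration for fluorescence microscopy, driven by Fourier
ring correlation (FRC) resolution measurements.

## The problem

Deconvolution and frequency-domain denoising both need to know how
blurry an image actually is — classically supplied as a measured or
theoretical point-spread function (PSF), which is tedious to obtain and
often wrong for the image at hand. FRC offers a way out: given two
images of the same field with independent noise, the normalized
cross-correlation of their Fourier transforms over concentric frequency
rings,

    FRC(r_i) = Σ_{r∈r_i} Re[F₁(r)·F₂*(r)] / sqrt( Σ|F₁|² · Σ|F₂|² ),

decays from 1 at low frequency to 0 where noise takes over. The
frequency where the curve drops below a threshold (the fixed 1/7
criterion, or an SNR-based curve) defines the effective resolution
d_min = 1/f_cross. That single number enables a family of *blind*
restoration methods, all implemented here:

- **Denoising** — use 1/d_min as the cutoff of an ideal, Butterworth or
  Gaussian low-pass filter (H = 0.5 and 0.607 at the cutoff for the
  latter two).
- **Blind Wiener deconvolution** — treat d_min as the FWHM of an
  effective Gaussian PSF (FWHM = 2√(2 ln 2)·σ) and invert it with
  regularized inverse filtering.
- **Blind Richardson–Lucy (RL)** — iterate the multiplicative RL update
  (optionally with a background term and total-variation
  regularization), recompute the FRC resolution of the estimate after
  every iteration, and stop when the per-iteration resolution gain
  ∇d_min rises above a threshold (−1, −0.2 or 0 nm/iteration); a
  second-difference failsafe aborts when the trend reverses, the
  signature of background over-fitting. The PSF can also be re-derived
  from FRC each iteration ("adjustive" RL).

Two practical extensions make this work beyond the textbook setting:

- **One-image FRC** — a single image is checkerboard-split into two
  sub-image pairs with independent noise; the averaged pair curves give
  a raw resolution that is then corrected by a monotone calibration
  fitted against the two-image reference (valid for the 1/7 threshold).
- **Sectioned FSC (SFSC)** — in 3D the axial resolution is typically ≥3×
  worse than lateral, so whole-shell FSC is nearly useless. SFSC
  correlates mirrored angular wedges rotated in α increments around an
  axis in the image plane, yielding resolution as a function of
  orientation — exactly what an anisotropic Gaussian PSF needs.

A synthetic-acquisition module (filament/point phantoms, Gaussian
blur, Poisson photon noise, paired realizations) makes every pipeline
testable end to end with known ground truth.

## Worked example

```python
import numpy as np
from frcrestore import (AcquisitionSpec, RLOptions, apply_window, frc_curve,
                        make_threshold, one_image_frc, resolution_from_curve,
                        restore, simulate_pair)
from frcrestore.calibrate import default_calibration

# simulate a confocal-like acquisition: filaments, 50 nm pixels,
# 250 nm PSF FWHM, 200 peak photons, two independent noise realizations
spec = AcquisitionSpec(seed=7)
phantom, (img_a, img_b) = simulate_pair(spec)

# two-image FRC (the gold standard)
curve = frc_curve(apply_window(img_a), apply_window(img_b))
ref = resolution_from_curve(curve, make_threshold("fixed_1_7", curve))
print(f"two-image FRC resolution: {ref.d_min_nm:.1f} nm")

# one-image FRC, raw and calibrated
cal = default_calibration()
_, raw = one_image_frc(img_a)
_, corrected = one_image_frc(img_a, calibration=cal)
print(f"one-image FRC: raw {raw.d_min_nm:.1f} nm, calibrated {corrected.d_min_nm:.1f} nm")

# blind Richardson-Lucy deconvolution with FRC-driven stopping
restored, report = restore(img_a, "blind_rl", calibration=cal,
                           options=RLOptions(max_iter=30, stop_grad_threshold=-1.0))
trace = report.trace
print(f"PSF FWHM used: {report.psf_fwhm_nm[0]:.1f} nm")
print(f"stopped after {len(trace.iterations)} iterations ({trace.stop_reason})")
print(f"resolution {report.input_d_min_nm:.1f} -> {report.output_d_min_nm:.1f} nm")
```

Output:

```
two-image FRC resolution: 237.1 nm
one-image FRC: raw 142.7 nm, calibrated 238.7 nm
PSF FWHM used: 238.7 nm
stopped after 3 iterations (threshold_reached)
resolution 238.7 -> 220.3 nm
```

The two-image measurement reads back the simulated 250 nm PSF within a
few percent. The raw one-image value is biased low — the sub-images
have twice the pixel pitch — and the calibration brings it onto the
two-image scale. Blind RL then sharpens the image until the resolution
gain per iteration falls below 1 nm; the restored estimate is both
higher-resolution (220 nm) and closer to the noiseless ground-truth
phantom (correlation 0.603 → 0.668 in this run).

The same pipelines are available from the shell:

```sh
frcrestore simulate /tmp/acq --seed 7
frcrestore frc /tmp/acq_real0.tif /tmp/acq_real1.tif
frcrestore rl /tmp/acq_real0.tif /tmp/restored.tif --stop-threshold -1
frcrestore fsc volume.tif --single-volume --alpha 15 --polar-csv polar.csv
```

## Layout

| module | contents |
| --- | --- |
| `frcrestore.image` | `ImageData` container, TIFF I/O with nm metadata, Hamming/Hann windowing, isotropic resampling, phase-correlation registration |
| `frcrestore.frc` | FRC curves, checkerboard one-image FRC, 1/7 and SNR thresholds, resolution extraction, calibration fitting |
| `frcrestore.fsc3d` | plain FSC, sectioned FSC with rotating dual wedges, sampling-anisotropy correction, single-volume splitting |
| `frcrestore.filters` | ideal/Butterworth/Gaussian low-pass transfer functions and frequency-domain filtering |
| `frcrestore.psf` | resolution → Gaussian PSF conversion and kernel rendering |
| `frcrestore.deconv` | Wiener and RL deconvolution, τ₁/η_k metrics, background estimation, FRC-driven stopping |
| `frcrestore.workflows` | end-to-end denoise / blind-Wiener / blind-RL pipelines with JSON reports |
| `frcrestore.synthetic` | phantom generation and simulated Poisson acquisitions |
| `frcrestore.calibrate` | one-image FRC calibration from a simulated pixel-size series |
| `frcrestore.cli` | `frcrestore` command-line interface |
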