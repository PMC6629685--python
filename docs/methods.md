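# Methods

## Resolution from spectral correlation

All resolution measurements reduce to one primitive: two arrays sharing
the same deterministic structure but independent noise are Fourier
transformed, the spectrum is partitioned into bins, and each bin gets
the normalized real cross-correlation
Σ Re(F₁·F₂*) / √(Σ|F₁|²·Σ|F₂|²). Bins are concentric rings (2D) or
shells (3D) one frequency pixel wide (bin width 1/N cycles/pixel,
N the largest image dimension), built by rounding each sample's radial
frequency to the nearest bin index. The DC-containing bin is kept —
it makes the "identical inputs give correlation 1" invariant visible —
but is never eligible as a threshold crossing. Bins with no samples or
zero power in either spectrum are dropped. Curves are reported up to
0.5 cycles/pixel by default; the spectrum corners (up to 0.5·√2) can be
requested but carry few samples and no additional physical bandwidth.

The resolution is the lowest frequency where the correlation falls
below the threshold, located by linear interpolation between the two
bracketing bins; d_min = 1/f_cross converted to nm via the pixel size.
If the curve never crosses, the result carries a `no_crossing` flag and
reports the sampling bound 2·pixel size — a bandwidth-limited value,
not a measurement. Two thresholds are provided: the fixed 1/7 criterion
(the 2D default), and the SNR-based curve
T = (SNR_e + (2√SNR_e+1)/√N) / (SNR_e + 1 + 2√SNR_e/√N) per-bin, whose
SNR_e = 0.5 instance (the "one-bit" criterion) is the 3D default. The
SNR curve uses each bin's own sample count, so sparsely populated bins
demand more correlation — important for the small sectioned-FSC wedges.

Before any spectral measurement the images are apodized with a
separable window. Hamming is the 2D default. For 3D sectioned
measurements the package windows with Hann instead: Hamming's sidelobe
floor (−43 dB, decaying only ~6 dB/octave) coherently leaks the
dominant shared lateral and DC power along the optical axis, and on
high-dynamic-range volumes this masquerades as axial correlation,
inflating axial resolution estimates erratically. Hann's ~18 dB/octave
decay suppresses the artifact at the cost of a slightly wider main
lobe, which affects all sections equally.

## One-image FRC and its calibration

A single image is split into four sub-images by pixel parity:
pair A = ((even,even), (odd,odd)), pair B = ((even,odd), (odd,even)).
Each sub-image has half the dimensions (odd trailing rows/columns are
truncated so the parity classes stay balanced) and twice the pixel
pitch, and the Poisson noise of disjoint pixel sets is independent.
The FRC curves of the two pairs are averaged bin-wise; averaging
suppresses the spectral asymmetries that a single diagonal pair shows
on strongly oriented structures. The frequency axis is deliberately
reported against the *original* pixel size, so the raw curve sits too
far right and the raw d_min underestimates. The correction is empirical:
a monotone quadratic (refit linear if the quadratic is non-monotone
over the data range) least-squares map from raw to two-image reference
d_min, fitted on a simulated series that mirrors the bench procedure —
a fixed-resolution scene (250 nm FWHM) imaged at pixel sizes from 29 to
113 nm, two scenes per size. The calibration is tied to the 1/7
threshold and stored with its fitted range; whole-curve correction is
out of scope. In-range leave-one-out residuals are a few percent.

For volumes, the analogous split keeps one lateral diagonal —
(even,even) vs (odd,odd) per plane — and sums consecutive z-layer pairs,
which preserves the volume proportions without introducing an axial
offset between the halves.

## Sectioned FSC geometry

Each Fourier shell is divided into dual wedges: a wedge of in-plane
angular size α plus its point-symmetric mirror, rotated in α increments
around an axis in the image plane (default y, α = 15°). A voxel's
in-plane angle — the inclination of its (f_axial, f_lateral) projection,
folded to [0, π) — selects the wedge. The wedge is additionally bounded
by an out-of-plane angle ϕ (default ϕ = α): voxels whose direction
leans more than ϕ/2 out of the rotation plane belong to no section.
Without this bound, every section contains the full tube of
frequencies around the rotation axis — predominantly *lateral*
information — and the axial sections inherit lateral resolution,
flattening the measured anisotropy to near unity on volumes with a
known threefold axial blur. With ϕ = α the axial/lateral ratio reads
back close to three at this package's default study conditions. At
α ≥ π the single section spans the sphere and SFSC reduces to plain
FSC exactly (tested to 1e−12); at ϕ = π the sections partition the
sphere and their shell counts sum to the plain-FSC counts.

Anisotropic sampling is compensated by scaling the voxel size of the
section at inclination θ by k(θ) = 1 + (z−1)|sin θ|, with z the
axial/lateral sampling ratio: no correction in-plane, full factor z
along the axis. (The multiplicative-only variant of this expression
vanishes at θ = 0, which would make lateral resolutions infinite; the
additive form is the physically meaningful reading.) Volumes are
expected isotropically resampled first — linear interpolation to the
finest axis spacing — after which z = 1 and no correction applies.

## From resolution to a PSF

The restoration methods treat d_min as the FWHM of an effective
Gaussian PSF, σ = d_min / (2√(2 ln 2)). Kernels are rendered separably
at the image's voxel spacing, sizes forced odd so the maximum sits on a
voxel (no half-pixel shift enters deconvolution), support ±4σ per axis
(>99.99% of mass), normalized to unit sum. In 3D the lateral FWHM comes
from the θ = 0 section and the axial FWHM from the widest section
(θ = 90°).

## Deconvolution

*Wiener.* O = H*/(|H|² + 1/SNR)·I on the spectrum of the reflect-padded
image (padding by one kernel half-support avoids circular wrap), the
kernel embedded with its center exactly on the FFT origin. The additive
constant is 1/SNR: small SNR values mean strong regularization. The CLI
defaults (SNR 0.1 in 2D, 0.005 in 3D) are the display choices
appropriate for real high-count confocal/STED data; the library
pipeline defaults to a blind estimate instead, SNR = (var − mean)/mean
of the image (the Poisson noise power equals the mean), because a fixed
display value does not transfer across photon budgets. Negative output
values are clipped for display; the raw result is available
(`clip=False`) and is what resolution measurements should use, since
clipping creates shared zero regions that inflate spectral correlation.

*Richardson–Lucy.* o_{k+1} = o_k · [(i/(h⊗o_k + b)) ⊗ h*], convolution
in the frequency domain with the same reflect padding, denominators
floored at machine epsilon, initialized at o₀ = the observed image.
The background b is zero, a supplied constant, or estimated blindly as
the mean of the below-threshold segment of an Otsu intensity mask.
Total-variation regularization divides the update by
1 − λ_TV·div(∇o/|∇o|) (λ_TV = 5×10⁻⁴ is the published operating value;
0 disables it).

After each iteration the estimate's resolution is measured with
one-image FRC (2D; calibrated when a calibration is supplied, so
stopping thresholds live on the physical scale) or split-volume FSC
(3D; a full sectioned measurement per iteration would dominate
runtime). The trace records d_min, its first difference ∇ (nm/it), the
second difference ∇², and the classical convergence metrics
τ₁ = Σ|o_k − o_{k−1}|/Σo_k and η (the fraction of RL-ratio pixels
outside ±ε of both 0 and 1; ε = 0.05 by default — the sources do not
fix a value). Stopping, checked in order:

1. *failsafe* — ∇ turned positive after a converging (negative-∇)
   trend, i.e. ∇² flipped the trend's sign: resolution is degrading,
   typically background over-fitting;
2. *threshold* — ∇ ≥ threshold. −1 nm/it stops after most of the gain,
   −0.2 near full convergence, 0 at maximal resolution. Thresholds are
   in nm per iteration and assume a nanometre-scale problem; a −∞
   threshold disables the rule rather than firing vacuously;
3. *max_iter*.

∇ is the raw first difference by default; an optional 3-point moving
average is available because per-iteration FRC is noisy. Adjustive mode
regenerates the Gaussian PSF from the latest resolution after every
iteration (in 3D by scaling all axes proportionally).

## Synthetic acquisitions

The generator emulates photon-limited fluorescence imaging: a phantom
(smoothed random-walk filaments with sub-pixel bilinear splatting, or
point emitters at a Poisson-drawn density, values in [0, 1]), blurred
with a known Gaussian PSF, scaled to a peak photon budget, plus a
constant background, then Poisson-sampled. Realizations share the
identical noiseless signal with independent noise streams derived from
the seed. Defaults are the package's study conditions: 256² (2D) /
96³ (3D) fields, 50 nm pixels, 250 nm lateral FWHM, axial FWHM 3×
lateral, 200 peak photons, zero background; the calibration series
spans pixel sizes 29–113 nm. These sizes keep every simulation-backed
test in seconds while leaving enough frequency bins (≥ 64 rings) for
stable crossings.

What the model deliberately omits — and what passing tests therefore do
not certify: read/dark noise, optical aberrations and non-Gaussian PSF
tails, scanning artifacts and drift, sample-dependent background
structure, and detector pixel cross-talk. On real data the FRC premise
(independent noise between the two inputs) must be provided by the
acquisition, and correlated noise will bias resolutions optimistically.

## Numerical notes and limitations

- FRC of two *identically filtered* images is invariant under any
  nonzero radial transfer function, so measuring "resolution gain" of a
  linear filter with FRC on the filtered pair is largely tautological;
  the meaningful claims for linear restoration are ground-truth
  fidelity (tested) and non-degradation of d_min.
- One-image FRC is invalid after any spatial filtering, because the
  filter correlates noise across the parity classes; measure the raw
  acquisition, or use a restored *pair*.
- Registration guarantees integer-pixel accuracy (phase correlation);
  subpixel refinement via upsampled cross-correlation is best effort.
- TIFF I/O stores spacing in nm (ImageJ-style metadata, µm inputs
  converted); files without any resolution metadata are rejected rather
  than defaulting to 1.
- Constant or empty inputs: degenerate FRC inputs yield `no_crossing`
  results; the RL update refuses an all-zero estimate (a fixed point);
  background estimation on a constant image returns the constant with a
  warning.
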