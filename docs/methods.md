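# Methods

## Model

The package treats spectral reconstruction from RGB as a calibration
problem, not a learning problem. Three assumptions carry the whole method:

1. **The camera is colorimetric up to a smooth distortion.** After sRGB
   linearization and the standard RGB→XYZ matrix, the camera's tristimulus
   estimate differs from the spectrometer-derived truth by an error that a
   low-order polynomial of (X, Y, Z) can absorb. Dark current appears as
   the constant term, colour-filter separation and colour shift as cross
   terms, response nonlinearity as squares and cubes. The default variable
   matrix V therefore has 14 terms — 1, X, Y, Z, X², Y², Z², XY, XZ, YZ,
   XYZ, X³, Y³, Z³ — and the correction C = XYZ_ref·pinv(V) is the global
   least-squares solution over the patch columns. Mixed-degree-3 monomials
   (X²Y, …) are omitted by default to keep the system well-conditioned
   with 24 patches; the spec is configurable.
2. **Scene reflectances occupy a low-dimensional smooth manifold.**
   Mean-centred PCA of the reference patch spectra retains the smallest k
   reaching a cumulative explained-variance target (default 0.999, cap
   k_max = 12). Reconstruction adds the mean back; without mean-centring
   the training set could not be reproduced exactly at full rank.
3. **Colour predicts the spectrum within that manifold.** PCA scores are
   regressed on the expanded corrected tristimulus values
   (M = Score·pinv(V_color), same default term family as V). This is where
   metamerism enters: two spectra with identical XYZ are indistinguishable,
   so the method works exactly to the extent that the target domain's
   spectra are colour-determined. Calibration targets should therefore
   cover the spectral family of the scenes to be converted (see
   `examples/02`).

Pseudo-inverses use a rank-revealing SVD with relative tolerance 1e-10;
underdetermined systems (patches < terms) raise rather than silently
regularize, and a rank-deficient design matrix is an explicit error.
PCA component signs are fixed (largest-magnitude loading positive) so the
fit is invariant to patch ordering.

## Conventions and numerical choices

- Wavelength grid: 380–780 nm at 1 nm (401 samples), shared by every
  spectral object; spectrometer exports are linearly interpolated onto it
  with endpoint hold. Integration is a rectangle rule at Δλ = 1 nm.
- Tristimulus values use the 0–100 luminance scale; the normalizer
  k = 100/Σ S(λ)ȳ(λ)Δλ depends only on the illuminant and ȳ.
- The CIE 1931 2° colour matching functions are evaluated from the
  published multi-lobe piecewise-Gaussian analytic fit (Wyman, Sloan &
  Shirley 2013), clipped to non-negative. The fit is within ~1% of peak of
  the tabulated observer; every quantity in the pipeline (camera
  simulation and spectrometer path alike) uses the same curves, so results
  are self-consistent. Illuminant presets: D65 (standard 10 nm table,
  interpolated), A (Planckian 2856 K, its defining formula), E (flat).
  The illuminant the physical rig used is generally unknown, so it is a
  required configuration item defaulting to D65.
- XYZ RMSE is pooled: one mean over 3 components × N patches, then one
  square root. Spectral RMSE is per patch over 401 bands, then averaged.
- Reconstructed reflectance is clipped to [0, 1.2] rather than 1.0:
  regression overshoot above 1 is informative (it is logged), and optically brightened
  whites and specular pixels can legitimately exceed 1; hard-clipping at
  1.0 would silently hide miscalibration.
- The sRGB transfer functions are extended sign-symmetrically outside
  [0, 1] in the internal vectorized path, so slightly out-of-gamut
  synthetic encodings round-trip exactly; the public scalar API validates
  its documented range.
- Image conversion processes rows in chunks (default 64) with bounded
  memory. Per-pixel linear algebra is accumulated term by term in a fixed
  order, so the cube is bit-identical for every chunk size. Cubes are
  stored float32 and written as ENVI text header + band-sequential binary
  (lossless float32, or a lossy uint16 mode mapping [0, 1.2] to 16 bits).
- ΔE defaults to the 2000 revision (current perceptual standard); the 1976
  Euclidean form is selectable.

## The synthetic data, and what passing tests show

`synth_patch_spectra` emulates a 24-patch colour target: a constant plus a
seeded combination of `basis_dim` overlapping raised cosines, globally
scaled into [0.02, 0.95] (exact rank ≤ basis_dim + 1). Because assumption 3
above is a property of the *data*, the generator enforces it: three
coordinates are drawn freely and carry the colour, while the remaining
metameric-black coordinates follow a fixed seeded polynomial (within the
default expansion's span) of the patch colour. This emulates the strong
colour–spectrum correlation of physical reflectance families. It also makes
the noiseless pipeline exactly identifiable — a deliberate property used by
the oracle tests: with an in-span camera distortion and no noise, recovery
to numerical precision is expected, and any failure is an implementation
defect, not model error.

`simulate_camera` is the forward model: raw channels integrate the
spectrum against the camera sensitivities (default: the colour matching
functions themselves, so the undistorted camera is exactly colorimetric),
then 3×3 channel crosstalk, per-channel gain, a compressive cubic response
(the recorded y solves a·y + b·y³ = x, so its correction a·Y + b·Y³ lies in
the default expansion span), sRGB encoding, dark-current offset and
Gaussian noise in 8-bit counts, and quantization — in that order.

`make_phantom` builds a vessel-bearing tissue scene: a smooth seeded
background reflectance, tortuous full-width vessel paths, and vessel
spectra attenuated by Gaussian dips (σ = 15 nm) at the hemoglobin band
centres (415/540 nm) with configurable depths. Ground-truth masks support
contrast measurements (Michelson contrast of region means).

What the synthetic conditions do **not** emulate: real hemoglobin
extinction shapes (the dips are Gaussian), scattering and depth effects,
specular highlights, spatially varying illumination, JPEG compression, and
camera sensitivities that differ structurally from the standard observer.
Passing tests therefore demonstrate the correctness and the noise
robustness of the algorithm under its own assumptions, not clinical image
quality; the simulation analogs (t1/t2 in `scripts/acceptance.py`) show
that under 8-bit quantization and 0.5-count sensor noise the synthetic rig
stays well inside the error envelope reported for physical
endoscope+spectrometer calibration of this method class.

## Problem sizes

The test suite and acceptance script run at the scale the method is
defined at: 24-patch targets, 401 bands, 128×128 phantoms, one full
640×640 frame conversion for the chunking/IO checks, 20 seeds for the
noise-robustness sweep. These sizes fully exercise every code path; the
conversion itself is linear in pixel count.

## Dataset utilities

Boxes are 0-based half-open pixel intervals internally; Pascal-VOC's
1-based inclusive corners are converted on read. YOLO conversion is the
standard centre/size normalization; the inverse round-trips within 0.5 px.
Splits are a seeded shuffle followed by a contiguous cut with floor
rounding (remainders to the last partition — 2741 items at 70:15:15 give
1918/411/412); with a grouping key (patient id), whole groups fill the
partitions in order against the same targets, so no patient straddles
partitions at the cost of slightly inexact ratios. Published descriptions
of such pipelines sometimes disagree on the exact ratio (60/20/20 vs
70:15:15 in the same report); the ratio here is an explicit parameter
defaulting to 70:15:15, and the tools are count-agnostic.

## Known limitations

- Reconstruction quality is bounded by metamerism: spectral features that
  barely move XYZ (narrow dips in low-ȳ regions, e.g. 415 nm) are mostly
  lost from 8-bit RGB; the 415-band contrast of a reconstructed cube is
  real but far below what a physical narrow-band filter measures.
- The correction and transformation are global; no spatially varying
  (lens-shading, vignetting) correction is attempted.
- The NBI display composite (415→G+B, 540→R, percentile normalization) is
  a documented convention, not a hardware emulation of any specific
  endoscope.
- A calibration model transfers only to images taken under the camera,
  illuminant and encoding it was fitted for.
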