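# Methods

`hsistain` implements a label-free virtual-staining workflow for retinal
cross-sections: transmission-mode hyperspectral image cubes are
calibrated, compressed to three principal-component channels, paired
with registered immunostained ground truth, and translated into
DAB-brightfield or immunofluorescence-like images by a conditional GAN,
scored with SSIM and PSNR.  Because no donor-tissue data can ship with
the package, a synthetic retinal phantom generates every input the
pipeline consumes; this note records the models, the defaults, and what
the synthetic results do and do not show.

## The imaging model and the phantom

A hypercube is an `(rows, cols, bands)` intensity array with a strictly
increasing wavelength axis; the default acquisition axis is 420–720 nm
in 2 nm steps (151 bands).  The phantom renders a layered cross-section
strip — six retinal bands (NFL, GCL, IPL, INL, OPL, ONL) delimited by
row fractions, a bright background above and below, and blood vessels
with wall and lumen — and plants two deposit classes with distinct
transmission signatures:

* **Tissue baseline** `b(λ) = 0.25 + 0.45·exp(−((λ−600)/120)²)`: a
  smooth transmittance bump peaking near 600 nm.  A Gaussian-like bump
  was chosen over a low-order polynomial deliberately: a quadratic
  peaked at 600 nm is itself almost flat over 550–650 nm (CV < 2%),
  which would make normal tissue mimic the pTau signature and leave no
  threshold able to separate the classes.
* **pTau ("flat hat")**: the baseline blended toward a constant plateau
  over 550–650 nm with a smoothstep taper of 20 nm on either side.  The
  plateau sits at 1.3× the baseline mean over the window at amplitude 1,
  so the signature is *elevated and uniform*; the coefficient of
  variation over the window decreases monotonically with amplitude.
  (The published signature gives the shape, not the magnitude; 1.3× was
  fixed so the plateau stays below transmittance 1.)
* **Aβ42 (short-wavelength deficit)**: the baseline multiplied by a
  Rayleigh-like attenuation `1 − 0.3·a·(500/λ)⁴`, i.e. a per-band
  transmission deficit proportional to `λ⁻⁴`, scaled to a 30% deficit at
  500 nm for amplitude 1 — consistent with the elevated-Rayleigh-
  scattering interpretation of the signature.

Pixel spectra are class transmittance × a separable smooth illumination
profile (quadratic vignette, identical in every band), plus additive
Gaussian noise (default SD 0.02 in normalized intensity) clipped to
[0, 1].  Deposit amplitudes are free parameters (defaults 0.6–1.0);
analysis code is kept scale-invariant so nothing depends on their
absolute values.

Paired ground truth is rendered analytically: DAB as a brown-on-light
brightfield image (brown chromaticity blended with the tissue tone in
proportion to amplitude; only the targeted marker stains), fluorescence
as red = pTau, green = Aβ42 amplitudes on black.  Vessels flagged with a
lumen artifact add spurious broadband signal inside the lumen in the
fluorescence image only, together with an artifact-free reference
rendering, so negative labeling can be exercised and scored.  A
per-pixel class mask (background 0, tissue 1, abeta 2, ptau 3, lumen 4)
records the truth.

**What the phantom does not emulate**: histological texture, paraffin
and sectioning artifacts, stain variability across patients, chromatic
aberration, depth sectioning, and deformation between the unstained and
stained acquisitions (registration is exercised by applying known warps
instead).  Passing tests therefore demonstrate that the algorithms are
implemented correctly and recover planted structure under realistic
noise; they say nothing about classification accuracy on human tissue.

## Calibration

The camera's wavelength-dependent response is corrected from a
blank-slide acquisition and a reference spectrometer reading of the
lamp: `coefficient(λ) = mean blank intensity at λ / spectrometer
intensity at λ`, with the spectrometer linearly interpolated onto the
cube axis (lamp spectra are smooth; the grid is 2 nm).  Calibration
*divides* by the coefficient — the only direction under which a blank
acquisition is flattened onto the reference profile; calibrating the
estimation blank reproduces the spectrometer-implied values exactly,
and a flat reference yields a flat profile to machine precision.
Color-checker fine-tuning, dark frames and spatial flat-fielding are
out of scope.

## Spectral signatures and categorization

Region spectra are per-band means over a selected pixel set (minimum 3
pixels), calibrated, then normalized to their own peak (area
normalization is available as an option).  Categorization computes
three scale-invariant scores on the normalized spectrum:

* `flatness = 1 − CV` over 550–650 nm,
* `level = mean(550–650) / mean(450–550)` (plateau prominence),
* `dip = 1 − mean(450–600) / mean(600–700)`.

Rules, in order: pTau if `flatness > 0.98` and `level > 1.5`; Aβ if
`dip > 0.19`; control otherwise.  The thresholds are midpoints between
the analytic scores of the phantom's generative spectra (tissue
baseline: flatness ≈ 0.967, level ≈ 1.41, dip ≈ 0.11; pTau amplitude 1:
flatness 1.0, level ≈ 1.73; Aβ amplitude 1: dip ≈ 0.25) and are
configurable.  A control-relative level criterion was rejected: after
peak normalization a true pTau plateau and a control spectrum both map
near 1 over the window, so their ratio (~1.05) carries almost no
signal.  Sensitivity floor: Aβ deposits below amplitude ≈ 0.6 score
under the dip threshold and read as control.  Strip scanning tiles the
cube with 5×5-px windows (window size is a default, not a finding) and
categorizes each; deposit-free, structure-free windows act as internal
controls.

## Registration

Stain images are aligned to the band with maximal spatial SD ("most
contrast").  The 8-bit complement `255 − pixel` makes both modalities
bright-on-dark; it is an involution, and because the similarity metric
is normalized cross-correlation (invariant to affine intensity maps)
complementing both images leaves the optimum unchanged.  The
nonreflective similarity (rotation, isotropic scale, translation; no
reflection) is found by a coarse grid over rotation (3° steps) × scale
(0.05 steps) at 1/4 resolution with phase-correlation translation
estimates, then Nelder–Mead refinement through a 3-level pyramid.  The
simplex is seeded with explicit per-parameter steps (1°, 0.02 log-scale,
1.5 px): Nelder–Mead's default perturbation vanishes for parameters
starting at zero, which silently freezes rotation and scale at the
identity.

Optional control-point refinement uses a local weighted mean of
second-degree polynomial transforms: around each landmark a quadratic
mapping is fitted on its K = 12 nearest control points (≥ 6 pairs
required — six coefficients per coordinate), and the final mapping is
the weighted mean of nearby polynomials with weight
`max(0, 1 − (d/r)²)`, `r` the distance to the Kth neighbor; locations
outside every radius fall back to the nearest landmark's polynomial.
The manual "is affine good enough" inspection is replaced by a
landmark-error threshold (default 2 px) that triggers LWM when control
points are supplied.  Interpolation is bilinear; out-of-frame pixels are
filled with the modality background (255 brightfield, 0 fluorescence).

## PCA compression

Pixel spectra (bands as features) are reduced to three principal
components fed in order into R, G, B.  The basis is fitted per strip —
all FOVs of one cross-section pooled — so patch channels are mutually
consistent and stitched predictions remain coherent; fitting can be
restricted by a background crop so most fitted spectra carry tissue
information.  Component signs are fixed (largest-|loading| entry
positive) for cross-platform determinism; each channel is min–max
scaled to 8 bits using the score range recorded at fit time, reused for
every projection from that basis; a zero-variance channel maps to 0.
On phantoms the three components capture ≈ 98% of pixel-spectrum
variance (the acceptance floor is 85%).

## Dataset construction and augmentation

Registered strip pairs are cut into fixed-size patches (256 px at full
scale; 64 px in the desk-scale preset).  The analysis region is held
out and tiled as test patches with 1/3–1/2 overlap so stitched
predictions have no intensity discontinuities; train patches tile the
remainder without overlap, never intersect the held-out region
(audited by coordinate arithmetic), and validation is a seeded random
subset of training.  Spurious lumen autofluorescence is negative-
labeled (zeroed) via the lumen mask, and remaining signal is
contrast-stretched so its 99th percentile maps to 255 — an upper-only
stretch, so black background and zero pixels are preserved.  Patches
whose ground truth is ≥ 99% background, or whose recorded registration
error exceeds 2 px, are discarded with a per-rule report.

Augmentation expands every pair exactly 12-fold with a fixed roster:
identity; ±8 px horizontal translations; ±5° and ±10° rotations;
horizontal and vertical flips; 0.9× and 1.1× scalings; one 1.0×1.1
anisotropic stretch.  The same transform is applied to both images of a
pair; non-identity variants additionally jitter the compressed image
alone by a uniform ±2 px translation, emulating residual registration
error between the modalities.  The roster and jitter magnitude are
package choices (the op families are given, their parameters are not)
and are configurable.

## Conditional GAN

The generator is a U-Net (strided-conv encoder, nearest-upsample
decoder, additive skip connections); the discriminator is a three-block
patch classifier whose sigmoid outputs score overlapping patches.  The
losses are exactly

    L(G;D) = −log D(G(x)) + λ·L1(G(x), y) − ν·log[(1 + SSIM(G(x), y))/2]
    L(D;G) = −log D(y) − log(1 − D(G(x)))

with λ = ν = 100.  Optimization is Adam (default moments), batch size
one under instance normalization, constant learning rate followed by a
linear decay to zero over the final epochs.  Full-scale defaults follow
the published recipe: 1e−5 (DAB) / 5e−6 (fluorescence), 135 epochs with
50 decayed, depth 6, base width 64; one model per target (dab_abeta,
dab_ptau, fluo_abeta, fluo_ptau), fluorescence channels trained
separately as single-channel targets.

Numerical choices: networks run in [−1, 1]; L1 and SSIM terms are
computed on [0, 1]-scaled images, so λ weights mean absolute error in
units of the dynamic range; the in-loss SSIM is the global per-patch
index with its gradient in closed form (verified against finite
differences in the tests); discriminator gradients are taken through
the logits, and reported probabilities are clamped to [1e−7, 1−1e−7]
only for logging, keeping losses finite.

The networks are built on a compact in-repo numpy layer engine with
hand-derived backpropagation (`_nn.py`) — single-sample conv/instance-
norm/activation layers and Adam.  Pure numpy keeps training
bit-reproducible under a fixed seed on a fixed platform and removes any
GPU/framework dependency; it is practical precisely because the
published recipe fixes batch size to one.

**Desk-scale preset** (`TrainConfig.tiny()`): depth 3, base width 16
(bottleneck capped at 64), 64×64 patches, 20 epochs with 10 decayed,
learning rate 2e−4 — the conventional rate for this conditional-GAN
family when training small models from scratch; the published rates are
tuned to multi-day full-scale runs and undertrain a 20-epoch surrogate.
On 200 synthetic DAB-pTau pairs this preset trains in a few minutes on
one CPU and reaches ≈ 24–43 dB held-out PSNR depending on strip content
(the acceptance floor is 20 dB).  These synthetic scores say nothing
about the real-data figures (SSIM 0.81–0.87, PSNR 21–33 dB), which
require donor images and full-scale training and are quoted as context
only.

## Stitching

Adjacent tiles are joined by scanning candidate overlap widths within
the nominal overlap (1/3 for FOV scans) ± a 10 px margin and a ±3 px
vertical jitter, scoring each by NCC over the shared strip — exhaustive,
so a constructed overlap is recovered exactly; constant tiles (all
candidates tied) are flagged degenerate and resolved to the nominal
offset.  The mosaic takes the left tile up to the middle of the overlap
and the right tile after; with blending enabled, a seam whose adjacent
columns differ by more than 5 gray levels on average has those columns
replaced by their mean.  With blending off, reassembling tiles cut from
one image is pixel-identical.

## Evaluation

SSIM follows the standard three-component form with c1 = (0.01·L)²,
c2 = (0.03·L)², L the dynamic range (255 for 8-bit).  The default
evaluation mode computes statistics globally over each patch — one SSIM
per output patch — matching per-patch reporting; a Gaussian-windowed
mode (σ = 1.5, ≈ 11-px support) is available and cross-checked against
scikit-image.  Since window mode and constants shift absolute values,
every report records the configuration used.  PSNR is
`10·log10(peak²/MSE)` with an infinity sentinel for identical images;
multi-channel images are scored per channel and averaged.  Model
reports aggregate per-patch values as mean ± sample SD (ddof = 1).

## Pipeline and reproducibility

The CLI (`hsistain`) exposes each stage as a subcommand; `run` executes
simulate → calibrate → compress → register → dataset → train → predict
→ stitch → evaluate from one YAML config.  Every stage persists its
artifacts in plain formats (multi-page TIFF + wavelength sidecar, PNG,
CSV, JSON), so any stage can be rerun from disk.  One global seed is
fanned out per stage by stable SHA-256 hashing of the stage name; the
run manifest records per-stage inputs, outputs, config hash, seed,
duration, and an artifact hash — reruns with identical config and seed
reproduce identical hashes.

## Problem sizes used in the shipped checks

Tests and the acceptance script run at desk scale as the package's own
choice of test geometry: phantom strips of 96×144 to 128×192 px with
151 bands, 5×5 scanning windows, 50 seeded registration recoveries, and
the tiny-mode GAN (240 pairs at 64×64, 200 train / 40 test, 20 epochs).

## Known limitations

* The phantom's deposit classes are spectrally pure per pixel; no
  subpixel mixing or overlapping deposits, which real tissue has.
* Similarity registration assumes overlapping content and fails
  gracefully (flagged degenerate) only for constant images; featureless
  but non-constant inputs can converge to low-score optima, guarded by
  a minimum-score error.
* The seam search is 1-D (strips are horizontal chains) with a small
  vertical jitter; it does not handle 2-D mosaics or rotation between
  tiles.
* LWM exactness at landmarks holds when the local quadratic model can
  interpolate its neighborhood (K near 6 or consistent deformations);
  with K = 12 and noisy landmarks it is a least-squares fit, which is
  the intended smoothing behavior.
* The numpy GAN trains small models quickly but does not scale to the
  full 256×256, depth-6, 150-epoch recipe on CPU; full-scale settings
  are provided for completeness, not benchmarked here.
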