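# Methods

This note records the models, conventions and design choices behind
`vsfpm`, and what the synthetic-phantom tests do and do not establish about
real tissue data.

## Optical model and conventions

The forward model is the standard thin-object, coherent FPM formulation.
The object is a 2-D complex transmission `O(r) = A(r) exp(i φ(r))` on a
fine grid of pixel size `p` μm; an LED at position `(x, y)` a height `h`
below the sample illuminates it with a plane wave of spatial frequency
`k_n = (sin θ_x, sin θ_y)/λ`, `sin θ = d/√(d² + h²)`. The camera records

```
I_n = | IFT{ P(k) · Ô(k + k_n) } |²
```

with `P` the objective pupil (circular indicator of radius `NA_obj/λ`, with
optional defocus phase `exp(i·2π/λ·z·√(1 − λ²k²))` and low-order Zernike
aberrations). Conventions used everywhere:

* spatial frequencies in cycles/μm of sample space; arrays indexed
  (row, col); unitary ("ortho") FFTs;
* spectrum shifts `k_n` are rounded to integer pixels of the object Fourier
  grid (sub-pixel residuals kept in stack metadata) — the common discrete
  FPM practice, and what makes the noiseless self-consistency test exact;
* downsampling to the sensor grid is Fourier cropping (ideal anti-aliased
  sampling), mean-preserving, so forward and inverse models agree exactly;
* the band-limit/cutoff frequency of the reconstruction is `NA_syn/λ`
  (dimensional analysis; one source prints the reciprocal, an apparent
  typo).

Scalar design quantities: effective magnification `M·f_tube/f_ref`
(4·200/180 = 4.44); depth of field `λ/NA²` with no refractive-index term —
this convention reproduces the ≈20 μm figure at λ = 530 nm, NA = 0.16;
field of view = sensor extent / effective magnification.

LED grid centring is `on_led` by default (one LED on the optical axis):
with the 22×22 / 7 mm / 81 mm geometry this reproduces the documented
177-LED circle (max illumination NA 0.54, outermost LED at √53·7 ≈ 51 mm,
NA_syn = 0.6925 ≈ 0.7), which the `between_leds` alternative does not.
Darkfield exposures follow `T_n = T_BF·(d_n/d_edge)²` where `d_edge` is the
radius at which the illumination NA equals `NA_obj`; only proportionality
is physically constrained, the normalisation (brightfield frames pinned at
`T_BF`, darkfield never below it) is this package's choice.

## Noise model

Frames are simulated in photoelectrons: `gain` (default 5000 e⁻ per unit
intensity at the brightfield exposure) scales the ideal intensity, Poisson
shot noise is applied, Gaussian read noise (σ = 2 e⁻) added, and values
clipped at a 30 000 e⁻ full well. Darkfield frames integrate `T_n/T_BF`
times longer before rescaling, which is exactly why the exposure law
improves their SNR. PRNU, dark current and finite LED étendue are not
modelled.

## Phantom

The generator emulates what a colonic mucosa section looks like to a
quantitative phase microscope, not histology itself: an irregular tissue
blob (thresholded low-pass noise), `n_crypts` annular crypts lined with
radially oriented ellipsoidal epithelial nuclei around an empty lumen,
Poisson-scattered stromal nuclei (default 8 per 1000 μm²), and band-limited
texture. Nuclei get lower phase (0.45×peak) than cytoplasm (0.75×peak),
encoding the lower nuclear refractive index; peak phase defaults to
1.5 rad to stay in the thin-object regime. All output is a deterministic
function of `(seed, params)`.

H&E rendering is Beer–Lambert, `rgb = exp(−Σ c_s A_s)`, with
Ruifrok–Johnston-style absorbance unit vectors (hematoxylin
[0.650, 0.704, 0.286] on nuclei, eosin [0.092, 0.954, 0.283] on the rest of
the tissue plus a weak nuclear term). Background carries zero concentration
and renders exactly white. The phase image "after staining" is the
unstained phase blurred (Gaussian, σ = 2 px) and scaled by 0.6 — a
qualitative stand-in for the contrast loss and smoothing that staining
chemistry causes; the parameters are exposed and make no physical claim.

What passing tests therefore show: the pipeline stages are mutually
consistent and recover known ground truth under this generative model. What
they do not show: performance on real tissue, where phase wrapping, thick
sections, partial coherence, scanner colour gamuts and biological
variability all enter.

## Reconstruction

The solver is the sequential (per-LED) Gauss–Newton scheme: modulus
substitution `ψ → √I_n · ψ/|ψ|` followed by regularised second-order
updates of the object spectrum window, `ΔO ∝ conj(P)·ΔΨ/(max|P|² + α)`,
and optionally of the pupil, `ΔP ∝ conj(O)·ΔΨ/(max|O|² + β)`, with
α = β = 10⁻³ relative. LEDs are visited from low to high |k_n| (the
low-resolution spectrum stabilises before darkfield extension), 10 epochs
by default, no momentum. The exact second-order variant behind the original
pipeline is not restated in public sources; this sequential form is
standard, robust, and verifiable by the noiseless self-consistency
("inverse crime") test, which recovers the in-band object to <1% NRMSE.
Divergence (data misfit rising three consecutive epochs) returns the best
iterate with a warning. Reconstructions carry a global complex gauge; all
comparisons first fit a single complex scalar (`align_global_phase`).

Post-processing follows the usual patchwise pipeline: 243-px raw patches at
3× upsampling with 25% overlap (the overlap scheme of the original
full-field stitch is not reconstructible from public numbers; 25% is this
package's choice), per-patch phase flattening (mean/std normalisation minus
a Gaussian-blurred copy — "kernel size 31" is interpreted as σ = 31/6
truncated to a 31×31 support), amplitude histogram matching to the
brightfield sum on a 256-bin min–max quantisation, linear-ramp blending,
Brown–Conrady undistortion (inverted by fixed-point iteration), and
angular-spectrum digital refocusing. Refocusing assumes defocus is a
propagation of the sample field; at large defocus combined with steep
illumination the per-band lateral walk-off makes the raw data itself
inconsistent with any single object, so refocusing is validated in the
propagate-then-capture regime and warns beyond the DOF scale.

## Registration and pair curation

SIFT keypoints (ratio test 0.75, cross-checked) feed RANSAC
(reprojection 3 px, up to 2000 trials) for a projective fit; registration
direction is unstained → stained, since the stained amplitude defines the
training grid. Mutual information is computed in **bits** from a 64×64
joint histogram of min–max-scaled patches; the 0.4 acceptance cutoff is
interpreted in those units (the original units are not stated) and a
warning fires if the estimator is re-binned while the default cutoff is
kept. All warps are bilinear with pixel centres at integer coordinates.

## Virtual staining

The cGAN follows pix2pix: a U-Net generator (stride-2 4×4 convs,
`log2(patch)` levels so the bottleneck is 1×1 on training patches, skip
concatenations) and a patch critic (three stride-2 levels + two stride-1),
BCE-with-logits adversarial loss plus λ = 100 L1, Adam (lr 2·10⁻⁴,
β = 0.5/0.999), random resize-crop jitter and mirror augmentation, 100
epochs at 256 px by default. The tensor backend is a small numpy layer
library with manual backpropagation, validated by numeric gradient checks.
Normalisation layers are instance-norm with running statistics used at
inference, making inference a spatially local map so tiled and untiled
outputs agree away from tile borders; tiles (default 1024 px, 64 px
overlap) are blended with linear ramps. Phase inputs are scaled to [−1, 1]
by the 1st/99th percentiles of the training phases, stored with the model.

The desk-scale surface is the smoke preset (64-px patches, width 8,
16 pairs, 50 epochs, minutes on one CPU): it must overfit — final generator
L1 below a quarter of epoch 1 — and reproduce training patches to <0.1 MAE.
Tissue-level claims (SSIM against real chemically stained images,
perceptual metrics, diagnostic concordance) require real slides and
full-scale training and are deliberately out of scope.

## Evaluation metrics

SSIM/RMSE/PSNR/PCC are computed globally per patch from the textbook
formulas with C1 = (0.01R)², C2 = (0.03R)² (a sliding-window SSIM exists
but is non-default, since evaluation is per 256-px patch). Colour
difference is CIE76 ΔE in Lab* under sRGB/D65. Decorrelation analysis uses
50 mask radii, 10 Gaussian high-pass pre-filters with σ geometric from 0.15
to 5 px, and Hann apodisation; the cutoff is the highest-frequency local
maximum over all curves, counting a curve still rising at Nyquist as
peaking there (a full-band image decorrelates nowhere below Nyquist).
Cutoffs are fractions of the analysed grid's Nyquist. Patch grids for
summary statistics are non-overlapping 256 px with an Otsu tissue mask;
masking is this package's choice.

## Problem sizes

Simulated experiments are sized for a single CPU: the resolution-gain twin
runs on 510×510 phantoms (= 3 × 170 raw pixels, so the 3× upsampling is an
exact integer ratio; three seeds averaged), the solver self-consistency
check on 150×150 grids with the full 177-LED plan, and the cGAN smoke runs
on 16 pairs of 64-px patches. These sizes were chosen as the smallest at
which each effect is cleanly measurable.

## Known limitations

* Thin-object, fully coherent model; no partial coherence, thick samples,
  or vignetting.
* The phantom is a consistency fixture, not a histological simulation.
* MI cutoff units are an interpretation (bits, 64 bins).
* LPIPS is not included (it requires externally trained network weights).
* The patchwise reconstruction treats raw-frame cropping as separable,
  which is approximate near patch borders — hence overlap-and-blend.
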