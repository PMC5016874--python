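# Methods

This note documents the models implemented in `mprkit`, the numerical choices
behind them, what the phantom generators do and do not emulate, and the known
limitations.

## Perfusion quantification

**Signal model.** Dual-contrast first-pass imaging acquires two
saturation-recovery slices per heartbeat: a blood-pool slice with a short
saturation delay (TD = 15 ms) and a tissue slice with a longer one
(TD = 57 ms). After proton-density normalization the signal is modelled as
ideal saturation recovery, `s = 1 − exp(−TD/T1)`, and inverted as
`T1 = −TD / ln(1 − s)`. The readout-perturbation correction of the underlying
FLASH readout is taken as unity; `signal_to_t1` is the single hook to replace
if a sequence-specific correction is required. Pre-contrast T1 is fixed at
1.55 s (blood) and 1.45 s (myocardium) rather than fitted per subject, which
is standard for this protocol at 7 T. Concentration is carried as
ΔR1 = 1/T1 − 1/T1₀; the (unknown) relaxivity multiplies both the arterial
input function (AIF) and the tissue function (TF) equally and cancels in the
deconvolution — absolute gadolinium concentration is deliberately out of
scope.

**Baseline handling.** Bolus arrival is detected on the AIF as the first
frame exceeding the provisional-baseline mean + 5 SD (first 5 frames); the
mean ΔR1 over pre-bolus frames is subtracted (`baseline="auto"`, overridable
with an explicit frame count or disabled). At short TD the blood baseline
signal is ≈ 0.0096, so noise can push individual samples outside the (0, 1)
domain of the inversion; `series_to_delta_r1` therefore clips samples into
[10⁻⁶, 1 − 10⁻⁶] by default (counting and logging them) while `strict=True`
raises instead. The baseline subtraction absorbs the first-order effect of
clipping.

**Fermi deconvolution.** The tissue curve is fitted as the causal discrete
convolution `c_tis(t_i) = Δt·(AIF ⊛ h)(t_i)` (trapezoidal quadrature on the
frame grid) with the Fermi impulse response

    h(t) = A / (1 + exp(k (t − d − τ)))   for t ≥ d,   0 otherwise,

parameters A (1/s), k (1/s), τ (s), d (s) all bounded below by zero. Flow is
the impulse-response value at contrast arrival, `MBF = h(d⁺)·60/ρ` with
`h(d⁺) = A/(1 + e^{−kτ})` and tissue density ρ = 1.05 g/mL.

A subtlety drives the optimizer design: between frame boundaries the sampled
model depends on d and τ only through d + τ, while `h(d⁺)` depends on τ
alone — a continuous delay therefore sits on a flat ridge of the objective
along which the flow estimate drifts by several percent, and the hard t < d
cutoff makes the residual discontinuous in d at every frame time. The delay
is consequently estimated on the frame grid (0 … 6 frames): for each
candidate d, (A, k, τ) are fitted by bounded least squares
(`scipy.optimize.least_squares`, trf) from three moment-based starts (the
flow scale is seeded by max(TF)/∫AIF; starts span slow and fast washout),
and the overall winner is the lowest RMSE, ties broken by the smaller delay.
Fitting is restricted to the first pass, defined as frames up to
t_peak + 1.5 × (peak-to-half-maximum recovery time) of the AIF
(configurable). A fit where no start converges is returned flagged, never as
a silent zero. On noiseless phantoms generated by the same forward model the
recovery is exact to numerical precision; at SNR 20 (see below) the bias is
about −2% with ~12% per-replicate scatter.

## LV volumetrics

Slice-summation (Simpson) volumetry without basal/apical partial-volume
correction: cavity volume = Σ endo-pixels × pixel area × slice thickness
(µL), myocardial mass = (epi − endo) volume × 1.05 mg/mm³ at end-diastole,
EF = 100·(EDV − ESV)/EDV. ED/ES phases are caller-identified labels;
`detect_ed_es` optionally picks them as the max/min cavity volume. Wall
thickness is measured on the mid slice by default: boundary pixels of the
endo and epi masks (mask minus its erosion) are binned into 24 angular
sectors about the cavity centroid, and per-sector thickness is the
difference of mean epicardial and endocardial boundary radii. Sectors
without boundary pixels are dropped with a warning; more than half dropped
is an error. The sector construction was chosen over centerline-chord
tracing for robustness on small rasterized mouse ventricles; both agree on
convex annular geometries. Papillary-muscle conventions and segmentation
itself are out of scope (masks are inputs).

## Strain and CURE

The deformation gradient at each material point is obtained by local
polynomial regression of displacement differences on reference-position
offsets within a neighbourhood of radius 3× the median point spacing: a
cubic basis with a Gaussian distance kernel (σ = radius/2.4), with F taken
from the linear coefficients (falling back to quadratic/affine for sparse
neighbourhoods). Regressing displacement *differences* keeps the identity
part of F exact; the higher-order terms absorb field curvature so one-sided
boundary neighbourhoods are unbiased at leading order — with a plain affine
fit the endocardial boundary error reaches ~15% on a realistic contraction,
versus < 1% for the weighted cubic. Exactly affine fields are reproduced to
machine precision, so rigid motions give Ecc = 0.

Ecc is the circumferential component of the Green–Lagrange tensor
E = ½(FᵀF − I) along the tangential unit direction at the reference
position. Profiles report segmental means over 24 sectors, the
count-weighted global mean, and subendocardial/subepicardial layer means
split at transmural depth 0.5 (matching the two layers conventionally
reported). Peak strain is the largest-magnitude (most negative, for
contraction) value over frames.

CURE is computed per frame from the DFT of segmental Ecc as s₀/(s₀+s₁)
(harmonic powers sₙ = |Xₙ|²), averaged over the included frames — by default
all frames from the first through the peak-strain frame. Frames whose total
s₀+s₁ is zero, or negligible relative to the series maximum (< 10⁻¹² of it,
i.e. pure round-off from a zero-strain frame), are excluded. The literature
contains both the power-ratio and its square root; the power ratio is the
default, `sqrt_convention=True` gives the other. Harmonics above the first
are ignored by the index's definition. Phase encoding/decoding
(φ = 2π·k_e·u) is supported only under the no-wrap condition |φ| < π;
phase unwrapping is deliberately out of scope.

## Glucose tolerance

Total (not baseline-subtracted) trapezoidal AUC over the sampled curve, with
incremental AUC available via `baseline_subtracted=True`; fasting glucose is
the t = 0 sample. Samples default to 0/10/30/60/90 min.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *measurement geometry and signal physics* of
the study with known ground truth:

- **AIF**: a normalized gamma-variate (t₀ = 0.6 s, t_peak = 1.8 s,
  peak ΔR1 = 12 s⁻¹, α = 3; optional recirculation bump, off by default).
  Real murine AIFs are measured, not modelled; the gamma-variate is the
  standard stand-in and its parameters here give a first pass of realistic
  width at a 500 bpm heart rate (frame interval 0.12 s, 60 frames).
- **Tissue curves**: generated by the same Fermi convolution the inverse
  problem assumes (decay 0.8 s⁻¹, width 1.5 s, delay one frame), so
  perfusion recovery tests are exact-model inversions — they validate the
  implementation, not the adequacy of the Fermi family for real myocardium.
- **Noise**: additive Gaussian on the normalized signal. SNR is quoted
  relative to the peak tissue enhancement, with the same absolute noise sd
  applied to blood and tissue series (one receiver-noise level per
  acquisition). Rician/magnitude bias is omitted: enhancements are small
  and ROI averaging dominates. Image phantoms (64×64) add independent
  per-pixel noise, so ROI-mean curves are correspondingly cleaner than
  single-pixel SNR suggests.
- **LV masks**: stacks of rasterized annuli (optionally with an ellipsoidal
  apical taper); the recorded truth is the slice-summation closed form of
  the same radii, and the ES phase follows area-preserving contraction, so
  myocardial volume is conserved exactly in the ground truth.
- **Strain**: incompressible cylinder contraction, r(R) = √(R² − Δ), with
  closed-form Ecc(R) = ½((r/R)² − 1); with reference radii 1.5/2.9 mm and a
  global peak of −0.14 this yields subendo ≈ −0.20 and subepi ≈ −0.097,
  matching the transmural gradient reported in vivo. Sampling uses polar
  rings whose point counts are multiples of 24 with half-step angular
  offsets, keeping the default sectors exactly balanced (no spurious
  binning harmonics). A first-harmonic modulation amplitude provides a
  controllable dyssynchrony dial for CURE tests. `solve_peak_ecc` finds the
  deformed endocardial radius reproducing a prescribed sampled global peak
  by bisection.
- **Cohorts**: per-subject values drawn independently from group
  mean ± SD per timepoint. The default effect profile encodes the studied
  phenotype — MPR preserved in controls (~2.4–2.5) but falling under HFD to
  ~1.6/1.4 at 18/24 weeks (SD 0.4), LV mass rising from ~85 to ~120 mg
  under HFD vs ~80–95 mg in controls (SD 10), EF preserved in both arms
  (values and SDs at the reported cohort scale), Ecc stable around −0.11 to
  −0.14 (SD 0.01–0.03), and body weight diverging from week 6. GTT profiles
  make HFD mice hyperglycemic and glucose-intolerant from week 12.
  Longitudinal correlation within subjects is *not* modelled (draws are
  independent across weeks), and strain phantoms are synchronous, so study
  CURE values sit at 1.0 rather than the in-vivo ~0.85.

The full-study generator derives every per-subject phantom from the drawn
values: stress flow = 4 mL/min/g × drawn MPR (draws truncated at 1.0, where
stress equals rest), annulus radii solve the drawn mass and EF at a fixed
EDV of 43 µL over 6 slices, and the cylinder deformation reproduces the
drawn peak Ecc. All seeds derive from the single study seed via
`numpy.random.SeedSequence` spawning, and tables are written with 10
significant digits, so identical configurations are byte-identical across
runs.

Passing tests on these phantoms demonstrates correct implementation of each
stage and correct end-to-end plumbing under the stated signal model; they do
not validate motion correction, segmentation, phase unwrapping, model
adequacy on real tissue, or reconstruction effects, all of which are outside
the package's scope.

## Problem sizes and tolerances

Default problem sizes were chosen to keep full verification runs in minutes
on one core: 60-frame curves, 64×64 dynamic images, 0.1 mm volumetric
phantom pixels, 0.2 mm strain point spacing (0.25 mm and 6 frames inside the
study generator), 100–200 Monte-Carlo replicates for noise studies, and
n = 4/group × 4 timepoints for determinism checks. Numerical tolerances used
in verification reflect what each construction justifies: 10⁻⁹ for analytic
round trips, ~2% for rasterization at 0.1 mm, 1% pointwise for strain at
0.2 mm sampling, 2% for noiseless deconvolution recovery, and 10% for
mean recovery under SNR-20 noise.

## Known limitations

- The Fermi parameterization with an explicit arrival delay is one of
  several variants in use; the delay quantization described above is this
  package's documented choice, not a claim about any other implementation.
- Ideal saturation-recovery inversion (no readout correction); see the hook
  noted above.
- ROI-level perfusion only — no pixel-wise flow maps.
- Group statistics are descriptive (mean ± SD, n); inferential testing is
  intentionally left to external statistics software, and the long-format
  per-subject table is written for that purpose.
- The wall-thickness estimator assumes an annulus-like topology in the
  measured slice and an interior cavity centroid.
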