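# mprkit

Quantitative analysis of serial cardiac MRI in mouse models of diet-induced
obesity: first-pass myocardial perfusion, left-ventricular (LV) structure and
function, myocardial strain, and glucose tolerance. The package implements the
full measurement chain used in longitudinal high-fat-diet (HFD) vs control
studies — where the key readout is a progressive fall in myocardial perfusion
reserve with preserved systolic function — together with analytic phantom
generators so that every stage is verifiable against closed-form ground truth.

It is intended for researchers analysing small-animal CMR data (or validating
such pipelines) who need transparent, tested reference implementations of:

- **Perfusion by Fermi-constrained deconvolution.** Dual-saturation-recovery
  first-pass imaging yields blood-pool (AIF) and myocardial (TF) signal
  curves. PD-normalized signals are inverted through the saturation-recovery
  model `s = 1 − exp(−TD/T1)` with fixed pre-contrast T1 (1.55 s blood,
  1.45 s myocardium), giving the concentration proxy ΔR1 = 1/T1 − 1/T1₀.
  The tissue curve is modelled as `c_tis = Δt · (AIF ⊛ h)` with the Fermi
  impulse response

  `h(t) = A / (1 + exp(k (t − d − τ)))` for `t ≥ d`, else 0,

  and myocardial blood flow is read off at contrast arrival:
  `MBF = h(d⁺) · 60 / ρ` (ρ = 1.05 g/mL). Myocardial perfusion reserve is
  `MPR = MBF_stress / MBF_rest`; relaxivity cancels in the ratio of ΔR1
  curves, so no gadolinium calibration is needed.
- **Cine LV volumetrics.** Slice-summation EDV/ESV/EF, LV mass
  (ρ = 1.05 mg/mm³) and sector-based end-diastolic/end-systolic wall
  thickness from endo/epicardial masks.
- **DENSE-style strain and synchrony.** Per-point deformation gradients from
  displacement fields by local polynomial regression, Green–Lagrange
  circumferential strain `Ecc = cᵀ·½(FᵀF − I)·c`, global and
  subendo/subepicardial peaks, and the circumferential uniformity ratio
  estimate `CURE = ⟨s₀/(s₀+s₁)⟩` from the spatial Fourier spectrum of
  segmental Ecc (1 = synchronous, 0 = pure first-harmonic dyssynchrony).
- **Glucose tolerance.** Fasting glucose and trapezoidal AUC from
  glucose–time tables sampled at 0/10/30/60/90 min.
- **Synthetic study generator.** Gamma-variate AIF, Fermi tissue curves,
  rendered NIfTI image stacks with ROI masks, annular LV mask stacks,
  incompressible-cylinder displacement fields (`Ecc(R) = ½((r/R)² − 1)` in
  closed form), GTT tables, and seeded two-arm longitudinal cohorts with
  configurable group effects.

## Worked example

Quantify perfusion on a rendered phantom whose true rest/stress flows are
4 and 10 mL/min/g:

```python
import numpy as np
from mprkit import synthetic as sy, perfusion as pf
from mprkit.core import AcquisitionParams

acq = AcquisitionParams()                      # TD 15/57 ms, 60 frames @ 0.12 s
phantom = sy.PhantomGroundTruth(mbf_rest=4.0, mbf_stress=10.0, seed=1)
rendered = sy.render_perfusion_series(phantom, acq)

results = {}
for cond, data in rendered.conditions.items():
    aif = pf.extract_roi_curve(data.aif_stack, data.blood_mask,
                               acq.frame_times, acq.td_aif, "blood")
    tf = pf.extract_roi_curve(data.tf_stack, data.myo_mask,
                              acq.frame_times, acq.td_tf, "tissue")
    results[cond] = pf.fermi_deconvolve(pf.series_to_delta_r1(aif),
                                        pf.series_to_delta_r1(tf),
                                        condition=cond)
    print(f"{cond}: MBF = {results[cond].mbf:.3f} mL/min/g")
print(f"MPR = {pf.compute_mpr(results['rest'], results['stress']).mpr:.3f}")
```

prints

```
rest: MBF = 4.000 mL/min/g
stress: MBF = 10.000 mL/min/g
MPR = 2.500
```

i.e. the deconvolution recovers both flows and their ratio exactly on a
noiseless phantom. An MPR of 2.5 is a normal perfusion reserve; values below
~2 indicate impaired microvascular vasodilation.

The same stages are available from the shell. For example, a glucose curve
(100, 200, 150, 120, 110 mg/dL at 0/10/30/60/90 min):

```
$ mprkit gtt --in glucose.csv --out gtt_summary.csv
 fasting_mg_dl  auc_mg_dl_min
           100          12500
```

A complete synthetic two-arm study (images, masks, displacement fields and
glucose tables for every subject × timepoint, plus a manifest) is produced by
`mprkit simulate --out study/ --seed 1 --n-per-group 8`, and analysed end to
end with `mprkit study --manifest study/manifest.json --out-dir results/`,
which writes a long-format per-subject table and a group mean ± SD summary.

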