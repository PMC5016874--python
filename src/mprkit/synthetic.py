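"""Ground-truth-labelled phantom generators for every pipeline stage.

The study's in-vivo inputs (first-pass image series, cine contours, DENSE
displacement fields, glucose tables) are emulated with analytic phantoms
whose true perfusion, volumes, strain and group effects are known in closed
form, so each analysis stage can be verified by parameter recovery:

* perfusion — a gamma-variate arterial input convolved with a Fermi impulse
  response gives the tissue curve; both are mapped to saturation-recovery
  signal and painted into small image stacks with ROI masks;
* LV geometry — annular short-axis mask stacks rasterised from analytic
  radii, with closed-form volumes, mass and wall thickness;
* strain — an incompressible (area-preserving) cylinder contraction with
  closed-form circumferential strain Ecc(R) = ½((r/R)² − 1);
* GTT — a baseline + gamma-shaped excursion glucose profile;
* cohorts — two-arm longitudinal tables drawing per-subject values from
  configurable group means ± SD per timepoint, mimicking the high-fat-diet
  vs control effect structure (MPR depressed late, LV mass rising, EF
  preserved).

All generators are bit-reproducible given their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (AcquisitionParams, ConcentrationCurve, RHO_MYOCARDIUM,
                   SignalTimeSeries, T1_BLOOD_DEFAULT, T1_MYO_DEFAULT)
from .lv_function import LVGeometry
from .perfusion import FermiParams, convolve_trapezoid, fermi_kernel
from .strain import StrainFrameSet

__all__ = [
    "GammaVariateAIF", "PhantomGroundTruth", "PerfusionSeriesData",
    "PerfusionPhantom", "CylinderDeformation", "GTTProfile", "CohortConfig",
    "gamma_variate_aif", "tissue_curve_from_fermi", "concentration_to_signal",
    "render_perfusion_series", "render_lv_masks", "ellipsoid_radii",
    "incompressible_epi_radius", "render_displacements", "solve_peak_ecc",
    "generate_gtt", "generate_cohort", "DEFAULT_EFFECT_PROFILE",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Perfusion forward model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaVariateAIF:
    """Normalised gamma-variate arterial input function.

    c(t) = c_peak · x^α · e^{α(1−x)} with x = (t − t0)/(t_peak − t0) for
    t > t0, zero before bolus arrival; the maximum is c_peak at t_peak.
    An optional recirculation bump (a second, scaled and delayed copy)
    is off by default.
    """

    t0: float = 0.6            # bolus arrival, s
    t_peak: float = 1.8        # s
    c_peak: float = 12.0       # peak ΔR1, 1/s
    alpha: float = 3.0
    recirc_fraction: float = 0.0   # amplitude of recirculation bump
    recirc_delay: float = 3.0      # s after t0

    def __post_init__(self) -> None:
        if not self.t_peak > self.t0:
            raise ValueError("t_peak must exceed t0")
        if self.c_peak <= 0 or self.alpha <= 0:
            raise ValueError("c_peak and alpha must be > 0")
        if self.recirc_fraction < 0:
            raise ValueError("recirc_fraction must be >= 0")

    def _single(self, t: np.ndarray, t0: float) -> np.ndarray:
        x = (t - t0) / (self.t_peak - self.t0)
        with np.errstate(invalid="ignore"):
            v = self.c_peak * np.power(np.maximum(x, 0.0), self.alpha) \
                * np.exp(self.alpha * (1.0 - x))
        return np.where(t > t0, v, 0.0)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        v = self._single(t, self.t0)
        if self.recirc_fraction > 0:
            v = v + self.recirc_fraction * self._single(t, self.t0 + self.recirc_delay)
        return v


def gamma_variate_aif(aif: GammaVariateAIF, times: np.ndarray) -> ConcentrationCurve:
    """Sample a gamma-variate AIF at the given (nondecreasing) times."""
    times = np.asarray(times, float)
    if times.size >= 2 and np.any(np.diff(times) < 0):
        raise ValueError("times must be nondecreasing")
    return ConcentrationCurve(times=times, delta_r1=aif(times))


def tissue_curve_from_fermi(aif_curve: ConcentrationCurve, fermi: FermiParams,
                            dt: float | None = None) -> ConcentrationCurve:
    """Forward tissue curve: trapezoidal causal convolution of AIF with h_fermi."""
    if dt is None:
        dt = aif_curve.dt
    t = aif_curve.times - aif_curve.times[0]
    c_tis = convolve_trapezoid(aif_curve.delta_r1, fermi(t), dt)
    return ConcentrationCurve(times=aif_curve.times, delta_r1=c_tis)


def concentration_to_signal(curve: ConcentrationCurve, acq: AcquisitionParams,
                            t1_0: float, noise_sd: float = 0.0,
                            seed=0, role: str = "blood") -> SignalTimeSeries:
    """Saturation-recovery signal from a ΔR1 curve.

    T1(t) = 1/(1/t1_0 + ΔR1(t)); s(t) = 1 − exp(−TD/T1(t)) plus zero-mean
    Gaussian noise.  Blood curves use the short AIF saturation delay, tissue
    curves the longer TF delay.
    """
    if t1_0 <= 0:
        raise ValueError("t1_0 must be > 0")
    td = acq.td_aif if role == "blood" else acq.td_tf
    r1 = 1.0 / t1_0 + np.asarray(curve.delta_r1, float)
    s = 1.0 - np.exp(-td * r1)
    if noise_sd > 0:
        s = s + _rng(seed).normal(0.0, noise_sd, size=s.shape)
    return SignalTimeSeries(times=curve.times, values=s, role=role, td=td)


@dataclass(frozen=True)
class PhantomGroundTruth:
    """True perfusion and relaxation parameters of a perfusion phantom."""

    mbf_rest: float = 4.0       # mL/min/g
    mbf_stress: float = 10.0    # mL/min/g
    t1_blood0: float = T1_BLOOD_DEFAULT
    t1_myo0: float = T1_MYO_DEFAULT
    noise_sd: float = 0.0       # normalized-signal units, per pixel
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mbf_rest > 0:
            raise ValueError("mbf_rest must be > 0")
        if self.mbf_stress < self.mbf_rest:
            raise ValueError("mbf_stress must be >= mbf_rest")
        if self.t1_blood0 <= 0 or self.t1_myo0 <= 0:
            raise ValueError("pre-contrast T1 values must be positive")

    @property
    def mpr(self) -> float:
        return self.mbf_stress / self.mbf_rest


def fermi_for_mbf(mbf: float, decay: float = 0.8, width: float = 1.5,
                  delay: float = 0.12,
                  rho_tissue: float = RHO_MYOCARDIUM) -> FermiParams:
    """Fermi parameters whose arrival value h(d⁺) encodes the given MBF."""
    h0 = mbf * rho_tissue / 60.0
    amplitude = h0 * (1.0 + np.exp(-decay * width))
    return FermiParams(amplitude, decay, width, delay)


@dataclass
class PerfusionSeriesData:
    """Rendered image data for one condition of a perfusion phantom."""

    aif_stack: np.ndarray      # (ny, nx, n_frames), AIF (short-TD) slice
    tf_stack: np.ndarray       # (ny, nx, n_frames), tissue (long-TD) slice
    blood_mask: np.ndarray     # (ny, nx) bool, on the AIF slice
    myo_mask: np.ndarray       # (ny, nx) bool, on the TF slice
    aif_truth: ConcentrationCurve
    tf_truth: ConcentrationCurve
    true_mbf: float


@dataclass
class PerfusionPhantom:
    """Rest + stress rendered series with acquisition sidecar and truth."""

    acq: AcquisitionParams
    truth: PhantomGroundTruth
    conditions: dict[str, PerfusionSeriesData]


def render_perfusion_series(phantom: PhantomGroundTruth,
                            acq: AcquisitionParams | None = None,
                            aif: GammaVariateAIF | None = None,
                            image_shape: tuple[int, int] = (64, 64),
                            ) -> PerfusionPhantom:
    """Render dual-slice first-pass image stacks for rest and stress.

    Blood-pool pixels of the AIF slice follow the blood signal curve and
    myocardial pixels of the TF slice the tissue curve; per-pixel Gaussian
    noise of sd ``phantom.noise_sd`` is added.  Deterministic given
    ``phantom.seed``.
    """
    acq = acq or AcquisitionParams()
    aif = aif or GammaVariateAIF()
    ny, nx = image_shape
    t = acq.frame_times
    aif_curve = gamma_variate_aif(aif, t)

    # circular blood pool and concentric myocardial annulus, pixel units
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r_pix = np.hypot(yy - cy, xx - cx)
    blood_mask = r_pix <= 0.15 * min(ny, nx)
    myo_mask = (r_pix > 0.20 * min(ny, nx)) & (r_pix <= 0.32 * min(ny, nx))

    root = np.random.SeedSequence(phantom.seed)
    conditions: dict[str, PerfusionSeriesData] = {}
    for child, (cond, mbf) in zip(root.spawn(2),
                                  [("rest", phantom.mbf_rest),
                                   ("stress", phantom.mbf_stress)]):
        rng = np.random.default_rng(child)
        tf_curve = tissue_curve_from_fermi(aif_curve, fermi_for_mbf(mbf))
        s_blood = concentration_to_signal(aif_curve, acq, phantom.t1_blood0,
                                          role="blood").values
        s_myo = concentration_to_signal(tf_curve, acq, phantom.t1_myo0,
                                        role="tissue").values
        # backgrounds at pre-contrast signal of the respective slice
        aif_stack = np.full((ny, nx, t.size),
                            1.0 - np.exp(-acq.td_aif / phantom.t1_blood0))
        tf_stack = np.full((ny, nx, t.size),
                           1.0 - np.exp(-acq.td_tf / phantom.t1_myo0))
        aif_stack[blood_mask, :] = s_blood
        tf_stack[myo_mask, :] = s_myo
        if phantom.noise_sd > 0:
            aif_stack = aif_stack + rng.normal(0, phantom.noise_sd, aif_stack.shape)
            tf_stack = tf_stack + rng.normal(0, phantom.noise_sd, tf_stack.shape)
        conditions[cond] = PerfusionSeriesData(
            aif_stack=aif_stack, tf_stack=tf_stack, blood_mask=blood_mask,
            myo_mask=myo_mask, aif_truth=aif_curve, tf_truth=tf_curve,
            true_mbf=mbf)
    return PerfusionPhantom(acq=acq, truth=phantom, conditions=conditions)


# ---------------------------------------------------------------------------
# LV mask phantoms
# ---------------------------------------------------------------------------

def ellipsoid_radii(r_base: float, n_slices: int) -> np.ndarray:
    """Per-slice radii of a half-ellipsoid (base to apex) of basal radius
    ``r_base``: r_i = r_base·sqrt(1 − (z_i/L)²) at slice centres."""
    z = (np.arange(n_slices) + 0.5) / n_slices
    return r_base * np.sqrt(np.maximum(1.0 - z ** 2, 0.0))


def incompressible_epi_radius(r_epi_ref: float, r_endo_ref: float,
                              r_endo_def: float) -> float:
    """Epicardial radius after an area-preserving (incompressible) deformation."""
    val = r_epi_ref ** 2 - r_endo_ref ** 2 + r_endo_def ** 2
    if val < 0:
        raise ValueError("deformation makes epicardial radius imaginary")
    return float(np.sqrt(val))


def render_lv_masks(phases: dict[str, tuple[np.ndarray | float, np.ndarray | float]],
                    n_slices: int = 6,
                    pixel_spacing: tuple[float, float] = (0.2, 0.2),
                    slice_thickness: float = 1.0,
                    image_shape: tuple[int, int] = (96, 96),
                    ) -> tuple[LVGeometry, dict]:
    """Rasterise analytic annular LV masks and return closed-form truth.

    ``phases`` maps a phase label to (endo radii, epi radii) in mm, scalar
    or per-slice.  Truth (slice-summation closed forms) per phase: cavity
    volume Σ πr_endo²·h (µL), myocardial volume Σ π(r_epi²−r_endo²)·h (mm³),
    mass = volume × 1.05 (mg), wall thickness of the mid slice (mm).
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    ny, nx = image_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r_mm = np.hypot((yy - cy) * pixel_spacing[0], (xx - cx) * pixel_spacing[1])

    masks: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    truth: dict[str, dict] = {}
    for label, (r_endo, r_epi) in phases.items():
        r_endo = np.broadcast_to(np.asarray(r_endo, float), (n_slices,)).copy()
        r_epi = np.broadcast_to(np.asarray(r_epi, float), (n_slices,)).copy()
        bad = (r_epi <= r_endo) & ~((r_epi == 0) & (r_endo == 0))
        if np.any(bad):
            raise ValueError(f"phase {label!r}: epicardial radius must "
                             "exceed endocardial radius")
        endo = np.stack([r_mm < re for re in r_endo])
        epi = np.stack([r_mm < rp for rp in r_epi])
        masks[label] = (endo, epi)
        cav = float(np.pi * np.sum(r_endo ** 2) * slice_thickness)
        myo = float(np.pi * np.sum(r_epi ** 2 - r_endo ** 2) * slice_thickness)
        mid = n_slices // 2
        truth[label] = {
            "cavity_volume_ul": cav,
            "myo_volume_mm3": myo,
            "mass_mg": myo * RHO_MYOCARDIUM,
            "wall_thickness_mm": float(r_epi[mid] - r_endo[mid]),
        }
    geom = LVGeometry(masks=masks, pixel_spacing=pixel_spacing,
                      slice_thickness=slice_thickness)
    return geom, truth


# ---------------------------------------------------------------------------
# Strain phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CylinderDeformation:
    """Area-preserving radial contraction of an annular cylinder.

    Material radius R maps to r(R) = sqrt(R² − (r_endo_ref² − r_endo_def²)),
    so r² − r_endo_def² = R² − r_endo_ref² for every R (incompressibility),
    and Ecc(R) = ½((r/R)² − 1) in closed form.
    """

    r_endo_ref: float = 1.5    # mm, end-diastolic endocardial radius
    r_epi_ref: float = 2.9     # mm
    r_endo_def: float = 1.0    # mm, deformed (end-systolic) endocardial radius
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.r_epi_ref > self.r_endo_ref > 0:
            raise ValueError("need r_epi_ref > r_endo_ref > 0")
        if self.r_endo_def <= 0:
            # r(R)² = R² − Δ ≥ r_endo_def² for all material R ≥ r_endo_ref,
            # so r_endo_def > 0 guarantees real deformed radii everywhere
            raise ValueError("deformation collapses the endocardium (r² < 0)")

    @property
    def delta(self) -> float:
        """Contracted area term r_endo_ref² − r_endo_def², mm²."""
        return self.r_endo_ref ** 2 - self.r_endo_def ** 2

    def deformed_radius(self, R: np.ndarray, scale: float = 1.0) -> np.ndarray:
        """r(R) at fractional contraction ``scale`` in [0, 1]."""
        val = np.asarray(R, float) ** 2 - scale * self.delta
        if np.any(val < 0):
            raise ValueError("deformation makes material radius imaginary")
        return np.sqrt(val)

    def ecc(self, R: np.ndarray, scale: float = 1.0) -> np.ndarray:
        """Closed-form circumferential strain ½((r/R)² − 1)."""
        R = np.asarray(R, float)
        return 0.5 * ((self.deformed_radius(R, scale) / R) ** 2 - 1.0)


def _annulus_points(deform: CylinderDeformation, spacing: float
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Polar point cloud over the annulus: (points, R, depth)."""
    radii = np.arange(deform.r_endo_ref, deform.r_epi_ref + 0.5 * spacing,
                      spacing)
    pts, R = [], []
    for rad in radii:
        # ring counts are multiples of 24 so the default angular sectors
        # stay balanced across rings (no spurious binning harmonics)
        n_theta = max(int(round(2 * np.pi * rad / spacing / 24.0)) * 24, 24)
        # half-step offset keeps points strictly inside angular sectors
        theta = 2 * np.pi * (np.arange(n_theta) + 0.5) / n_theta
        pts.append(np.column_stack([rad * np.cos(theta), rad * np.sin(theta)]))
        R.append(np.full(n_theta, rad))
    pts = np.vstack(pts) + np.asarray(deform.center)
    R = np.concatenate(R)
    depth = (R - deform.r_endo_ref) / (deform.r_epi_ref - deform.r_endo_ref)
    return pts, R, np.clip(depth, 0.0, 1.0)


def render_displacements(deform: CylinderDeformation, spacing: float = 0.2,
                         n_frames: int = 10,
                         frame_interval: float = 0.012,
                         modulation_amplitude: float = 0.0,
                         ) -> tuple[StrainFrameSet, dict]:
    """Displacement fields of a contracting cylinder over a systolic ramp.

    The contraction fraction follows a smooth sin² ramp from 0 (frame 0) to
    1 (last frame), so peak strain occurs at the final frame.  An optional
    first-harmonic dyssynchrony ``modulation_amplitude`` m scales the local
    contraction as (1 + m·cosθ), giving a controllable non-uniform
    segmental strain pattern (closed-form Ecc then applies only at m = 0).

    Returns the frame set and a truth dict with per-point closed-form Ecc at
    peak, the true global/layer peaks, and the per-frame contraction scale.
    """
    pts, R, depth = _annulus_points(deform, spacing)
    scales = np.sin(0.5 * np.pi * np.arange(n_frames) / (n_frames - 1)) ** 2 \
        if n_frames > 1 else np.array([1.0])
    theta = np.arctan2(pts[:, 1] - deform.center[1],
                       pts[:, 0] - deform.center[0])
    mod = 1.0 + modulation_amplitude * np.cos(theta)
    rhat = (pts - np.asarray(deform.center)) / R[:, None]
    disp = np.zeros((n_frames, pts.shape[0], 2))
    for f, s in enumerate(scales):
        r_def = deform.deformed_radius(R, scale=s)
        u_mag = (r_def - R) * mod
        disp[f] = u_mag[:, None] * rhat
    frames = StrainFrameSet(points=pts, displacements=disp,
                            center=np.asarray(deform.center, float),
                            frame_times=np.arange(n_frames) * frame_interval,
                            depth=depth)
    ecc_peak = deform.ecc(R, scale=1.0)
    truth = {
        "ecc_peak_per_point": ecc_peak,
        "R": R,
        "global_peak_ecc": float(ecc_peak.mean()),
        "subendo_peak_ecc": float(ecc_peak[depth < 0.5].mean()),
        "subepi_peak_ecc": float(ecc_peak[depth >= 0.5].mean()),
        "scales": scales,
    }
    return frames, truth


def solve_peak_ecc(target_global_ecc: float,
                   r_endo_ref: float = 1.5, r_epi_ref: float = 2.9,
                   spacing: float = 0.2) -> CylinderDeformation:
    """Cylinder deformation whose sampled global peak Ecc equals the target.

    Solves for the deformed endocardial radius by bisection on the
    closed-form mean strain over the sampling grid.
    """
    if not -0.5 < target_global_ecc < 0:
        raise ValueError("target peak Ecc must be in (−0.5, 0) for contraction")
    from scipy.optimize import brentq

    def mean_ecc(r_def: float) -> float:
        d = CylinderDeformation(r_endo_ref, r_epi_ref, r_def)
        _, R, _ = _annulus_points(d, spacing)
        return float(d.ecc(R).mean()) - target_global_ecc

    r_def = brentq(mean_ecc, 1e-3 * r_endo_ref, r_endo_ref - 1e-9,
                   xtol=1e-12)
    return CylinderDeformation(r_endo_ref, r_epi_ref, r_def)


# ---------------------------------------------------------------------------
# GTT and cohort generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GTTProfile:
    """Glucose excursion: baseline + gamma-shaped rise peaking at t_peak."""

    baseline: float = 95.0     # mg/dL, fasting
    excursion: float = 180.0   # mg/dL peak rise above baseline
    t_peak: float = 20.0       # min

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        x = t / self.t_peak
        return self.baseline + self.excursion * x * np.exp(1.0 - x)


DEFAULT_GTT_TIMES = np.array([0.0, 10.0, 30.0, 60.0, 90.0])


def generate_gtt(profile: GTTProfile,
                 sample_times: np.ndarray = DEFAULT_GTT_TIMES,
                 noise_sd: float = 0.0, seed=0,
                 subject: str = "", group: str = "", week: int | None = None):
    """Sample a glucose profile at GTT draw times with seeded noise.

    Values driven negative by noise are clipped to 0; the record of clipped
    samples is returned alongside.
    """
    from .gtt import GTTRecord
    sample_times = np.asarray(sample_times, float)
    if np.any(np.diff(sample_times) < 0):
        raise ValueError("sample_times must be nondecreasing")
    g = profile(sample_times)
    if noise_sd > 0:
        g = g + _rng(seed).normal(0.0, noise_sd, size=g.shape)
    clipped = g < 0
    g = np.clip(g, 0.0, None)
    record = GTTRecord(times=sample_times, glucose=g, subject=subject,
                       group=group, week=week)
    return record, clipped


#: Group means ± SD per timepoint (weeks on diet), shaped after the study's
#: longitudinal trends: MPR preserved in controls but depressed in HFD mice
#: at 18–24 weeks; LV mass progressively increased under HFD; EF preserved
#: in both arms (magnitudes from the reported cohort tables); body weight
#: diverging from week 6.
DEFAULT_EFFECT_PROFILE: dict[str, dict[str, dict[int, tuple[float, float]]]] = {
    "mpr": {
        "control": {6: (2.5, 0.4), 12: (2.5, 0.4), 18: (2.5, 0.4), 24: (2.4, 0.4)},
        "hfd":     {6: (2.4, 0.4), 12: (2.2, 0.4), 18: (1.6, 0.4), 24: (1.4, 0.4)},
    },
    "lv_mass": {
        "control": {6: (80.0, 10.0), 12: (83.0, 10.0), 18: (86.0, 10.0), 24: (95.0, 10.0)},
        "hfd":     {6: (85.0, 10.0), 12: (95.0, 10.0), 18: (110.0, 10.0), 24: (120.0, 10.0)},
    },
    "ef": {
        "control": {6: (61.0, 8.0), 12: (64.0, 12.0), 18: (64.0, 9.0), 24: (67.0, 8.0)},
        "hfd":     {6: (66.0, 8.0), 12: (65.0, 8.0), 18: (69.0, 12.0), 24: (74.0, 11.0)},
    },
    "ecc": {
        "control": {6: (-0.14, 0.02), 12: (-0.13, 0.02), 18: (-0.12, 0.03), 24: (-0.12, 0.01)},
        "hfd":     {6: (-0.13, 0.02), 12: (-0.12, 0.01), 18: (-0.11, 0.02), 24: (-0.14, 0.02)},
    },
    "body_weight": {
        "control": {6: (28.0, 2.0), 12: (31.0, 2.5), 18: (33.0, 3.0), 24: (35.0, 3.0)},
        "hfd":     {6: (38.0, 3.0), 12: (44.0, 3.5), 18: (48.0, 4.0), 24: (51.0, 4.0)},
    },
}


@dataclass
class CohortConfig:
    """Two-arm longitudinal cohort: per-timepoint group means ± SD."""

    n_per_group: int = 8
    timepoints: tuple[int, ...] = (6, 12, 18, 24)
    effect_profile: dict = field(
        default_factory=lambda: DEFAULT_EFFECT_PROFILE)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for metric, groups in self.effect_profile.items():
            for grp, weeks in groups.items():
                for wk, (mu, sd) in weeks.items():
                    if sd < 0:
                        raise ValueError(
                            f"negative SD for {metric}/{grp}/week {wk}")


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a per-subject longitudinal measurement table.

    One row per subject × week with columns for each configured metric,
    drawn independently from the group's Normal(mean, SD) at that week.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    metrics = list(config.effect_profile)
    rows = []
    for grp in ("control", "hfd"):
        for i in range(config.n_per_group):
            subject = f"{grp}_{i+1:02d}"
            for wk in config.timepoints:
                row = {"subject": subject, "group": grp, "week": wk}
                for m in metrics:
                    mu, sd = config.effect_profile[m][grp][wk]
                    row[m] = mu + sd * rng.standard_normal() if sd > 0 else mu
                rows.append(row)
    return pd.DataFrame(rows)
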