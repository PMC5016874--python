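"""Shared domain types and physical constants for the cardiac-MR pipeline.

Units follow the conventions of small-animal CMR: times in seconds,
lengths in mm, relaxation rates in 1/s, volumes in µL (1 mm³ = 1 µL),
mass in mg, perfusion in mL/min/g.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

#: Pre-contrast longitudinal relaxation time of blood at 7 T, seconds.
T1_BLOOD_DEFAULT = 1.55
#: Pre-contrast longitudinal relaxation time of myocardium at 7 T, seconds.
T1_MYO_DEFAULT = 1.45
#: Myocardial tissue density, g/mL (equivalently mg/mm³).
RHO_MYOCARDIUM = 1.05


class SchemaError(ValueError):
    """A structured input (sidecar, manifest, table) violates its schema."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Sequence timing and geometry of the dual-contrast first-pass acquisition.

    The sequence interleaves two saturation-recovery slices per heartbeat:
    a short saturation delay (``td_aif``) for the blood-pool slice, where
    contrast concentrations are high, and a longer delay (``td_tf``) for
    the tissue slice, where the signal change is small.

    Parameters
    ----------
    tr, te : float
        Repetition and echo time, seconds.
    flip_angle : float
        Readout flip angle, degrees, in (0, 90].
    td_aif, td_tf : float
        Saturation delays of the blood-pool and tissue slices, seconds.
        ``td_aif < td_tf``.
    frame_interval : float
        Time between consecutive frames (one frame per heartbeat), seconds.
    n_frames : int
        Number of frames in the dynamic series.
    pixel_spacing : tuple of float
        In-plane pixel size, mm/pixel, (row, column).
    slice_thickness : float
        Slice thickness, mm.
    """

    tr: float = 2.1e-3
    te: float = 1.2e-3
    flip_angle: float = 15.0
    td_aif: float = 0.015
    td_tf: float = 0.057
    frame_interval: float = 0.12  # 500 bpm heart rate
    n_frames: int = 60
    pixel_spacing: tuple[float, float] = (0.2, 0.2)
    slice_thickness: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tr", "te", "td_aif", "td_tf", "frame_interval",
                     "slice_thickness"):
            if getattr(self, name) <= 0:
                raise SchemaError(f"{name} must be strictly positive")
        if self.n_frames < 1:
            raise SchemaError("n_frames must be >= 1")
        if not 0 < self.flip_angle <= 90:
            raise SchemaError("flip_angle must be in (0, 90] degrees")
        if not self.td_aif < self.td_tf:
            raise SchemaError("td_aif must be < td_tf (blood slice uses the "
                              "short saturation delay)")
        if len(self.pixel_spacing) != 2 or any(p <= 0 for p in self.pixel_spacing):
            raise SchemaError("pixel_spacing must be a positive 2-vector")

    @property
    def frame_times(self) -> np.ndarray:
        """Frame mid-times, seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pixel_spacing"] = list(self.pixel_spacing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        required = {"tr", "te", "flip_angle", "td_aif", "td_tf",
                    "frame_interval", "n_frames", "pixel_spacing",
                    "slice_thickness"}
        missing = required - set(d)
        if missing:
            raise SchemaError(
                "acquisition sidecar missing field(s): " + ", ".join(sorted(missing)))
        extra = set(d) - required
        if extra:
            raise SchemaError(
                "acquisition sidecar has unknown field(s): " + ", ".join(sorted(extra)))
        d = dict(d)
        d["pixel_spacing"] = tuple(d["pixel_spacing"])
        return cls(**d)


Role = Literal["blood", "tissue"]


@dataclass
class SignalTimeSeries:
    """PD-normalized ROI-mean signal vs time for one first-pass series.

    ``values`` are dimensionless normalized signals in [0, 1); ``td`` is the
    saturation delay that produced them (blood and tissue slices differ).
    """

    times: np.ndarray
    values: np.ndarray
    role: Role
    td: float
    n_baseline: int | None = None  # pre-bolus frame count, if known

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have the same length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.td <= 0:
            raise ValueError("saturation delay td must be positive")


@dataclass
class ConcentrationCurve:
    """Contrast-agent concentration proxy ΔR1(t) = 1/T1(t) − 1/T1₀, in 1/s.

    Relaxivity is not calibrated: ΔR1 is proportional to gadolinium
    concentration with the same constant in blood and tissue, so the
    constant cancels in the deconvolution.
    """

    times: np.ndarray
    delta_r1: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.delta_r1 = np.asarray(self.delta_r1, dtype=float)
        if self.times.shape != self.delta_r1.shape:
            raise ValueError("times and delta_r1 must have the same length")

    @property
    def dt(self) -> float:
        """Uniform sampling interval; raises if sampling is non-uniform."""
        d = np.diff(self.times)
        if d.size == 0:
            raise ValueError("curve has fewer than 2 samples")
        if not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
            raise ValueError("curve sampling is not uniform")
        return float(d[0])
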