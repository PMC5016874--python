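"""Glucose-tolerance test summarisation: fasting glucose and trapezoidal AUC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GTTRecord", "auc_trapezoid", "fasting_glucose"]


@dataclass
class GTTRecord:
    """One subject's glucose-vs-time curve after an i.p. glucose bolus.

    times : minutes post-injection, nondecreasing, starting at 0 (the
        fasting draw taken before injection).
    glucose : mg/dL, nonnegative.
    """

    times: np.ndarray
    glucose: np.ndarray
    subject: str = ""
    group: str = ""
    week: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.glucose = np.asarray(self.glucose, float)
        if self.times.shape != self.glucose.shape:
            raise ValueError("times and glucose must have the same length")
        if self.times.size and np.any(np.diff(self.times) < 0):
            raise ValueError("times must be nondecreasing")
        if np.any(self.glucose < 0):
            raise ValueError("glucose values must be nonnegative")


def auc_trapezoid(record: GTTRecord, baseline_subtracted: bool = False) -> float:
    """Area under the glucose curve, mg/dL·min, by the trapezoidal rule.

    Default is total AUC; with ``baseline_subtracted`` the fasting (t = 0)
    value is subtracted from every sample first (incremental AUC).
    """
    if record.times.size < 2:
        raise ValueError("AUC requires at least 2 samples")
    g = record.glucose
    if baseline_subtracted:
        g = g - fasting_glucose(record)
    return float(np.trapezoid(g, record.times))


def fasting_glucose(record: GTTRecord) -> float:
    """The pre-injection (t = 0) glucose value, mg/dL."""
    at_zero = np.flatnonzero(record.times == 0)
    if at_zero.size == 0:
        raise ValueError("no fasting (t = 0) sample in record")
    return float(record.glucose[at_zero[0]])
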