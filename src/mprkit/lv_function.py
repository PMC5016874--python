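"""Cine LV volumetrics: EDV, ESV, EF, mass and wall thickness from contours.

Volumes use slice-summation (Simpson) volumetry over short-axis endo/epi
masks: cavity volume = Σ endo-area × slice thickness, myocardial mass =
Σ (epi − endo) area × thickness × ρ with ρ = 1.05 mg/mm³.  Wall thickness
is measured per angular sector about the cavity centroid as the difference
of mean epicardial and endocardial boundary radii.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import RHO_MYOCARDIUM

logger = logging.getLogger(__name__)

__all__ = ["LVGeometry", "LVIndices", "cavity_volume", "ejection_fraction",
           "lv_mass", "wall_thickness", "detect_ed_es", "lv_indices"]


@dataclass
class LVGeometry:
    """Per-slice, per-phase endo/epi masks with pixel geometry.

    masks : dict mapping phase label -> (endo, epi), each boolean arrays of
        shape (n_slices, ny, nx).  Endo must be a subset of epi everywhere.
    pixel_spacing : (row, col) mm/pixel.
    slice_thickness : mm.
    """

    masks: dict[str, tuple[np.ndarray, np.ndarray]]
    pixel_spacing: tuple[float, float]
    slice_thickness: float

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValueError("at least one phase is required")
        if self.slice_thickness <= 0 or any(p <= 0 for p in self.pixel_spacing):
            raise ValueError("pixel geometry must be strictly positive")
        for phase, (endo, epi) in self.masks.items():
            endo = np.asarray(endo).astype(bool)
            epi = np.asarray(epi).astype(bool)
            if endo.ndim != 3 or endo.shape != epi.shape:
                raise ValueError(f"phase {phase!r}: masks must be matching "
                                 "(n_slices, ny, nx) stacks")
            bad = endo & ~epi
            if bad.any():
                s = int(np.flatnonzero(bad.any(axis=(1, 2)))[0])
                raise ValueError(f"endocardial mask exceeds epicardial mask "
                                 f"at phase {phase!r}, slice {s}")
            self.masks[phase] = (endo, epi)

    @property
    def pixel_area(self) -> float:
        return float(self.pixel_spacing[0] * self.pixel_spacing[1])

    def phase(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        if label not in self.masks:
            raise KeyError(f"phase {label!r} not present "
                           f"(have {sorted(self.masks)})")
        return self.masks[label]


@dataclass(frozen=True)
class LVIndices:
    """Volumetric and geometric indices of LV structure and function."""

    edv: float   # µL
    esv: float   # µL
    ef: float    # %
    mass: float  # mg (end-diastolic)
    edwt: float  # mm
    eswt: float  # mm


def cavity_volume(geom: LVGeometry, phase: str) -> float:
    """LV cavity volume at a phase, µL (1 mm³ = 1 µL), by slice summation."""
    endo, _ = geom.phase(phase)
    return float(endo.sum() * geom.pixel_area * geom.slice_thickness)


def ejection_fraction(edv: float, esv: float) -> float:
    """EF (%) = 100 · (EDV − ESV) / EDV."""
    if edv <= 0:
        raise ValueError("EDV must be > 0")
    return 100.0 * (edv - esv) / edv


def lv_mass(geom: LVGeometry, phase: str,
            rho_myo: float = RHO_MYOCARDIUM) -> float:
    """Myocardial mass at a phase, mg: (epi − endo) volume × density."""
    endo, epi = geom.phase(phase)
    myo_vol = (epi.sum() - endo.sum()) * geom.pixel_area * geom.slice_thickness
    return float(myo_vol * rho_myo)


def _boundary_polar(mask2d: np.ndarray, center: np.ndarray,
                    spacing: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """(theta, radius_mm) of the boundary pixels of a 2-D mask."""
    boundary = mask2d & ~ndimage.binary_erosion(mask2d)
    rows, cols = np.nonzero(boundary)
    dy = (rows - center[0]) * spacing[0]
    dx = (cols - center[1]) * spacing[1]
    return np.arctan2(dy, dx), np.hypot(dy, dx)


def wall_thickness(geom: LVGeometry, phase: str, n_sectors: int = 24,
                   slice_index: int | None = None) -> tuple[float, np.ndarray]:
    """Mean and per-sector wall thickness (mm) at a phase.

    For each angular sector about the cavity centroid, thickness = mean
    epicardial boundary radius − mean endocardial boundary radius.  Sectors
    lacking boundary pixels are dropped with a warning; if more than half
    are dropped the measurement fails.  By default the mid slice is used
    (the conventional single-slice wall-thickness measurement); pass
    ``slice_index`` to choose another.
    """
    if n_sectors < 8:
        raise ValueError("n_sectors must be >= 8")
    endo, epi = geom.phase(phase)
    s = endo.shape[0] // 2 if slice_index is None else slice_index
    endo2d, epi2d = endo[s], epi[s]
    if not endo2d.any() or not epi2d.any():
        raise ValueError(f"empty mask in measured slice {s} at phase {phase!r}")
    center = np.array(ndimage.center_of_mass(endo2d))

    th_endo, r_endo = _boundary_polar(endo2d, center, geom.pixel_spacing)
    th_epi, r_epi = _boundary_polar(epi2d, center, geom.pixel_spacing)
    edges = np.linspace(-np.pi, np.pi, n_sectors + 1)
    per_sector = np.full(n_sectors, np.nan)
    for k in range(n_sectors):
        in_endo = (th_endo >= edges[k]) & (th_endo < edges[k + 1])
        in_epi = (th_epi >= edges[k]) & (th_epi < edges[k + 1])
        if in_endo.any() and in_epi.any():
            per_sector[k] = r_epi[in_epi].mean() - r_endo[in_endo].mean()
    dropped = int(np.isnan(per_sector).sum())
    if dropped:
        logger.warning("wall_thickness: %d/%d sectors had no boundary pixels",
                       dropped, n_sectors)
    if dropped > n_sectors // 2:
        raise ValueError(f"degenerate mask: {dropped}/{n_sectors} sectors "
                         "lack boundary pixels")
    return float(np.nanmean(per_sector)), per_sector


def detect_ed_es(geom: LVGeometry) -> tuple[str, str]:
    """Identify ED (max cavity volume) and ES (min) among available phases."""
    vols = {p: cavity_volume(geom, p) for p in geom.masks}
    ed = max(vols, key=vols.get)
    es = min(vols, key=vols.get)
    return ed, es


def lv_indices(geom: LVGeometry, ed: str = "ED", es: str = "ES",
               n_sectors: int = 24) -> LVIndices:
    """EDV, ESV, EF, ED mass and ED/ES wall thickness in one pass."""
    edv = cavity_volume(geom, ed)
    esv = cavity_volume(geom, es)
    return LVIndices(
        edv=edv, esv=esv, ef=ejection_fraction(edv, esv),
        mass=lv_mass(geom, ed),
        edwt=wall_thickness(geom, ed, n_sectors)[0],
        eswt=wall_thickness(geom, es, n_sectors)[0],
    )
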