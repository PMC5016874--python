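"""Lagrangian circumferential strain and CURE synchrony from displacement fields.

Displacement-encoded (DENSE) imaging yields an in-plane displacement vector
per myocardial material point per cardiac frame.  The deformation gradient F
is estimated at each point by least squares over a local neighbourhood, the
Green-Lagrange strain is E = ½(FᵀF − I), and the circumferential component
Ecc = cᵀEc is taken along the circumferential unit direction c at the
reference position.  Segmental Ecc profiles around the circumference feed
the circumferential uniformity ratio estimate (CURE), a spatial-Fourier
synchrony index: 1 for perfectly uniform contraction, 0 for a pure
first-harmonic (e.g. septal-vs-lateral) pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "StrainFrameSet", "EccProfile", "CUREResult",
    "deformation_gradient", "circumferential_strain", "ecc_profiles",
    "peak_global_ecc", "compute_cure", "encode_phase", "decode_phase",
]


@dataclass
class StrainFrameSet:
    """Material points, per-frame displacements and geometry for strain analysis.

    points : (N, 2) reference positions, mm.
    displacements : (F, N, 2) displacement of each point in each frame, mm.
    center : (2,) LV cavity centre in the reference frame, mm.
    frame_times : (F,) seconds.
    depth : (N,) transmural depth in [0, 1]; 0 = endocardium, 1 = epicardium.
    """

    points: np.ndarray
    displacements: np.ndarray
    center: np.ndarray
    frame_times: np.ndarray
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float)
        self.displacements = np.asarray(self.displacements, float)
        self.center = np.asarray(self.center, float)
        self.frame_times = np.asarray(self.frame_times, float)
        self.depth = np.asarray(self.depth, float)
        n = self.points.shape[0]
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be (N, 2)")
        if self.displacements.shape != (self.frame_times.size, n, 2):
            raise ValueError("displacements must be (n_frames, N, 2)")
        if self.depth.shape != (n,):
            raise ValueError("depth must be (N,)")
        if np.any(self.depth < 0) or np.any(self.depth > 1):
            raise ValueError("transmural depth must lie in [0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frame_times.size


@dataclass
class EccProfile:
    """Segmental, global and layer-resolved Ecc per frame.

    segmental : (F, n_sectors) mean Ecc per angular sector (NaN if empty).
    counts : (F, n_sectors) valid point counts per sector.
    global_ecc : (F,) count-weighted spatial mean.
    subendo / subepi : (F,) layer means (depth < 0.5 / depth ≥ 0.5).
    """

    segmental: np.ndarray
    counts: np.ndarray
    global_ecc: np.ndarray
    subendo: np.ndarray
    subepi: np.ndarray
    frame_times: np.ndarray


@dataclass
class CUREResult:
    """CURE index with the per-frame zeroth/first harmonic powers."""

    cure: float
    s0: np.ndarray
    s1: np.ndarray
    included_frames: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.cure <= 1.0 + 1e-12:
            raise ValueError("CURE must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Deformation gradient and strain
# ---------------------------------------------------------------------------

def deformation_gradient(points: np.ndarray, displacements: np.ndarray,
                         radius: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Per-point 2×2 deformation gradient by local least squares.

    For each point, relative deformed positions of its neighbours within
    ``radius`` are regressed on a cubic polynomial of the relative
    reference positions (local polynomial regression with a Gaussian
    distance kernel, σ = radius/2.4), and F is read from the linear
    coefficients.  The higher-order terms absorb field curvature so that
    boundary points, whose neighbourhoods are one-sided, do not bias F at
    leading order; neighbourhoods too small for the cubic fit fall back to
    quadratic (< 10 neighbours) and then affine (< 6).  On exactly affine
    data every variant returns the affine map's matrix at every point.
    The default radius is 3× the median nearest-neighbour spacing.

    Returns
    -------
    F : (N, 2, 2) array
    valid : (N,) bool — False where the neighbourhood is insufficient or
        collinear (those points are excluded from profiles downstream).
    """
    points = np.asarray(points, float)
    displacements = np.asarray(displacements, float)
    n = points.shape[0]
    tree = cKDTree(points)
    if radius is None:
        nn, _ = tree.query(points, k=2)
        radius = 3.0 * float(np.median(nn[:, 1]))
    F = np.broadcast_to(np.eye(2), (n, 2, 2)).copy()
    valid = np.ones(n, dtype=bool)
    neighbor_lists = tree.query_ball_point(points, r=radius)
    for i, idx in enumerate(neighbor_lists):
        idx = np.asarray(idx)
        dX = points[idx] - points[i]
        # regress displacement differences: F = I + ∂u/∂X keeps the
        # identity part exact regardless of conditioning
        du = displacements[idx] - displacements[i]
        # need >= 3 neighbours (incl. self) spanning the plane
        G = dX.T @ dX
        if idx.size < 3 or np.linalg.matrix_rank(G, tol=1e-10 * radius ** 2) < 2:
            valid[i] = False
            continue
        if idx.size >= 6:
            # no constant term: dX = dx = 0 at the centre point itself
            xi, eta = dX[:, 0], dX[:, 1]
            cols = [xi, eta, xi ** 2, xi * eta, eta ** 2]
            if idx.size >= 10:
                cols += [xi ** 3, xi ** 2 * eta, xi * eta ** 2, eta ** 3]
            basis = np.column_stack(cols)
            w = np.exp(-(np.hypot(xi, eta) / (radius / 2.4)) ** 2)
            coef, *_ = np.linalg.lstsq(basis * w[:, None], du * w[:, None],
                                       rcond=None)
            F[i] = F[i] + coef[:2].T
        else:
            # ∂u/∂X minimizes ||du - J dX||²  =>  J = (du' dX)(dX' dX)^{-1}
            F[i] = F[i] + np.linalg.solve(G, dX.T @ du).T
    if not valid.all():
        logger.warning("%d/%d points had insufficient/collinear neighbourhoods",
                       int((~valid).sum()), n)
    return F, valid


def circumferential_strain(F: np.ndarray, points: np.ndarray,
                           center: np.ndarray) -> np.ndarray:
    """Ecc = cᵀ E c with E = ½(FᵀF − I), c ⟂ the radius at each reference point."""
    F = np.asarray(F, float)
    rel = np.asarray(points, float) - np.asarray(center, float)
    r = np.linalg.norm(rel, axis=1)
    if np.any(r == 0):
        raise ValueError("a material point coincides with the centre; "
                         "circumferential direction undefined")
    c = np.stack([-rel[:, 1], rel[:, 0]], axis=1) / r[:, None]
    E = 0.5 * (np.einsum("nji,njk->nik", F, F) -
               np.eye(2))
    return np.einsum("ni,nij,nj->n", c, E, c)


def ecc_profiles(frames: StrainFrameSet, n_sectors: int = 24,
                 radius: float | None = None) -> EccProfile:
    """Segmental/global/layer Ecc for every frame of a displacement set."""
    if n_sectors < 4:
        raise ValueError("n_sectors must be >= 4")
    rel = frames.points - frames.center
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    sector = np.floor((theta + np.pi) / (2 * np.pi) * n_sectors).astype(int)
    sector = np.clip(sector, 0, n_sectors - 1)
    endo_layer = frames.depth < 0.5

    F_frames = frames.n_frames
    segmental = np.full((F_frames, n_sectors), np.nan)
    counts = np.zeros((F_frames, n_sectors), dtype=int)
    global_ecc = np.zeros(F_frames)
    subendo = np.zeros(F_frames)
    subepi = np.zeros(F_frames)
    for f in range(F_frames):
        F, valid = deformation_gradient(frames.points,
                                        frames.displacements[f], radius)
        ecc = circumferential_strain(F, frames.points, frames.center)
        if not valid.any():
            raise ValueError(f"all points invalid in frame {f}")
        global_ecc[f] = ecc[valid].mean()
        subendo[f] = ecc[valid & endo_layer].mean() if (valid & endo_layer).any() else np.nan
        subepi[f] = ecc[valid & ~endo_layer].mean() if (valid & ~endo_layer).any() else np.nan
        for s in range(n_sectors):
            m = valid & (sector == s)
            counts[f, s] = int(m.sum())
            if counts[f, s]:
                segmental[f, s] = ecc[m].mean()
    return EccProfile(segmental=segmental, counts=counts, global_ecc=global_ecc,
                      subendo=subendo, subepi=subepi,
                      frame_times=frames.frame_times)


def peak_global_ecc(profile: EccProfile) -> dict[str, float]:
    """Peak (largest-magnitude) global and layer Ecc over frames.

    For a contracting ventricle this is the most negative value; the signed
    extremum is returned, along with the frame index where the global peak
    occurs.
    """
    g = profile.global_ecc
    if g.size < 2:
        raise ValueError("need at least 2 frames to locate peak strain")
    if not np.isfinite(g).any():
        raise ValueError("no finite global Ecc values")
    i_peak = int(np.nanargmax(np.abs(g)))

    def _extremum(x: np.ndarray) -> float:
        x = x[np.isfinite(x)]
        return float(x[np.argmax(np.abs(x))]) if x.size else float("nan")

    return {
        "global": float(g[i_peak]),
        "subendo": _extremum(profile.subendo),
        "subepi": _extremum(profile.subepi),
        "peak_frame": i_peak,
    }


# ---------------------------------------------------------------------------
# CURE
# ---------------------------------------------------------------------------

def compute_cure(segmental: np.ndarray, included: np.ndarray | str = "systole",
                 sqrt_convention: bool = False) -> CUREResult:
    """Circumferential uniformity ratio estimate from segmental Ecc.

    Per frame the discrete Fourier transform of Ecc over sectors gives
    harmonic powers s_n = |X_n|²; CURE = mean over included frames of
    s0/(s0+s1) (or its square root under ``sqrt_convention``).  Frames with
    s0 + s1 = 0 or any non-finite sector are excluded; "systole" includes
    frames from the first through the global-peak-strain frame.
    """
    segmental = np.asarray(segmental, float)
    if segmental.ndim != 2:
        raise ValueError("segmental must be (n_frames, n_sectors)")
    n_frames, n_sectors = segmental.shape
    if n_sectors < 4:
        raise ValueError("n_sectors must be >= 4")

    if isinstance(included, str):
        if included != "systole":
            raise ValueError("included must be 'systole' or an index array")
        means = np.nanmean(segmental, axis=1)
        i_peak = int(np.nanargmax(np.abs(means)))
        frame_idx = np.arange(i_peak + 1)
    else:
        frame_idx = np.asarray(included, dtype=int)

    s0 = np.zeros(frame_idx.size)
    s1 = np.zeros(frame_idx.size)
    usable = np.zeros(frame_idx.size, dtype=bool)
    for j, f in enumerate(frame_idx):
        seg = segmental[f]
        if not np.all(np.isfinite(seg)):
            continue
        X = np.fft.fft(seg)
        s0[j] = np.abs(X[0]) ** 2
        s1[j] = np.abs(X[1]) ** 2
        usable[j] = (s0[j] + s1[j]) > 0
    # a zero-strain frame carries only round-off power; treat it as zero
    total = s0 + s1
    if total.max() > 0:
        usable &= total > 1e-12 * total.max()
    if not usable.any():
        raise ValueError("no usable frames for CURE (all excluded)")
    ratio = s0[usable] / (s0[usable] + s1[usable])
    if sqrt_convention:
        ratio = np.sqrt(ratio)
    return CUREResult(cure=float(min(ratio.mean(), 1.0)), s0=s0, s1=s1,
                      included_frames=frame_idx[usable])


# ---------------------------------------------------------------------------
# Phase encoding (no-wrap mapping only; unwrapping is out of scope)
# ---------------------------------------------------------------------------

def encode_phase(displacements: np.ndarray, ke: float) -> np.ndarray:
    """Map displacement (mm) to DENSE phase φ = 2π·ke·u (ke in cycles/mm).

    Requires |φ| < π everywhere (no wrapping); violations raise.
    """
    phase = 2.0 * np.pi * ke * np.asarray(displacements, float)
    if np.any(np.abs(phase) >= np.pi):
        raise ValueError("phase would wrap (|2π·ke·u| >= π); reduce ke")
    return phase


def decode_phase(phase: np.ndarray, ke: float) -> np.ndarray:
    """Inverse of :func:`encode_phase` under the no-wrap precondition."""
    if ke <= 0:
        raise ValueError("ke must be > 0")
    return np.asarray(phase, float) / (2.0 * np.pi * ke)
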