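"""Readers/writers for the study's file formats and the study orchestrator.

On-disk layout (one directory per subject × timepoint, produced by
``write_study_inputs`` and consumed by ``run_study``):

    <root>/manifest.json                      study manifest
    <root>/subjects.csv                       drawn per-subject ground truth
    <root>/sub-<id>/wk<WW>/perfusion/<cond>/  aif.nii, tf.nii,
                                              blood_mask.nii, myo_mask.nii,
                                              acq.json
    <root>/sub-<id>/wk<WW>/cine/              <phase>_endo.nii, <phase>_epi.nii,
                                              geometry.json
    <root>/sub-<id>/wk<WW>/strain/            points.csv, displacements.csv,
                                              meta.json
    <root>/sub-<id>/wk<WW>/gtt.csv

Images and masks are NIfTI (x, y, frame for dynamics; slice, y, x for mask
stacks); sidecars are JSON; tables are CSV written with 10 significant
digits so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import gtt as gtt_mod
from . import lv_function as lvf
from . import perfusion as perf
from . import strain as strain_mod
from . import synthetic as synth
from .core import AcquisitionParams, SchemaError

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"

__all__ = [
    "save_stack", "load_stack", "save_mask", "load_mask",
    "write_sidecar", "read_sidecar", "write_table", "read_table",
    "StudyManifest", "read_manifest", "write_study_inputs", "run_study",
    "analyze_perfusion_dir", "analyze_cine_dir", "analyze_strain_dir",
    "analyze_gtt_file",
]


# ---------------------------------------------------------------------------
# Standard-format primitives
# ---------------------------------------------------------------------------

def save_stack(path, array: np.ndarray, pixel_spacing=(0.2, 0.2),
               slice_thickness: float = 1.0) -> None:
    """Write an image stack as NIfTI with pixel geometry in the affine."""
    affine = np.diag([pixel_spacing[0], pixel_spacing[1], slice_thickness, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(array, np.float64), affine), str(path))


def load_stack(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), np.float64)


def save_mask(path, mask: np.ndarray, pixel_spacing=(0.2, 0.2),
              slice_thickness: float = 1.0) -> None:
    affine = np.diag([pixel_spacing[0], pixel_spacing[1], slice_thickness, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(mask, np.uint8), affine), str(path))


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5


def write_sidecar(path, acq: AcquisitionParams) -> None:
    Path(path).write_text(json.dumps(acq.to_dict(), indent=2, sort_keys=True))


def read_sidecar(path) -> AcquisitionParams:
    return AcquisitionParams.from_dict(json.loads(Path(path).read_text()))


def write_table(df: pd.DataFrame, path) -> None:
    """CSV with ≥ 9 significant digits for lossless numeric round trips."""
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Study manifest
# ---------------------------------------------------------------------------

@dataclass
class StudyManifest:
    """Subjects, group assignment and per-timepoint modality paths."""

    root: Path
    timepoints: list[int]
    subjects: list[dict]   # {id, group, weeks: {week: {modality: relpath}}}

    def __post_init__(self) -> None:
        for sub in self.subjects:
            for key in ("id", "group", "weeks"):
                if key not in sub:
                    raise SchemaError(f"manifest subject entry missing {key!r}")


def read_manifest(path) -> StudyManifest:
    path = Path(path)
    d = json.loads(path.read_text())
    for key in ("timepoints", "subjects"):
        if key not in d:
            raise SchemaError(f"manifest missing field {key!r}")
    return StudyManifest(root=path.parent, timepoints=list(d["timepoints"]),
                         subjects=d["subjects"])


# ---------------------------------------------------------------------------
# Per-modality writers (phantom → files) and analyzers (files → metrics)
# ---------------------------------------------------------------------------

def _write_perfusion_condition(outdir: Path, data: synth.PerfusionSeriesData,
                               acq: AcquisitionParams) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    ps = acq.pixel_spacing
    save_stack(outdir / "aif.nii", data.aif_stack, ps, acq.slice_thickness)
    save_stack(outdir / "tf.nii", data.tf_stack, ps, acq.slice_thickness)
    save_mask(outdir / "blood_mask.nii", data.blood_mask, ps, acq.slice_thickness)
    save_mask(outdir / "myo_mask.nii", data.myo_mask, ps, acq.slice_thickness)
    write_sidecar(outdir / "acq.json", acq)


def analyze_perfusion_dir(cond_dir, t1_blood0: float | None = None,
                          t1_myo0: float | None = None,
                          condition: str = "rest",
                          baseline="auto") -> perf.PerfusionResult:
    """Full signal chain for one rendered condition directory."""
    cond_dir = Path(cond_dir)
    acq = read_sidecar(cond_dir / "acq.json")
    t = acq.frame_times
    aif_s = perf.extract_roi_curve(load_stack(cond_dir / "aif.nii"),
                                   load_mask(cond_dir / "blood_mask.nii"),
                                   t, acq.td_aif, role="blood")
    tf_s = perf.extract_roi_curve(load_stack(cond_dir / "tf.nii"),
                                  load_mask(cond_dir / "myo_mask.nii"),
                                  t, acq.td_tf, role="tissue")
    # stacks are stored already PD-normalized; the explicit step is kept so
    # raw-signal inputs only need a different pd_value
    aif_s = perf.normalize_by_pd(aif_s, 1.0)
    tf_s = perf.normalize_by_pd(tf_s, 1.0)
    aif_c = perf.series_to_delta_r1(aif_s, t1_blood0, baseline=baseline)
    tf_c = perf.series_to_delta_r1(tf_s, t1_myo0, baseline=baseline)
    return perf.fermi_deconvolve(aif_c, tf_c, condition=condition)


def _write_cine(outdir: Path, geom: lvf.LVGeometry) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for phase, (endo, epi) in geom.masks.items():
        save_mask(outdir / f"{phase}_endo.nii", endo, geom.pixel_spacing,
                  geom.slice_thickness)
        save_mask(outdir / f"{phase}_epi.nii", epi, geom.pixel_spacing,
                  geom.slice_thickness)
    meta = {"pixel_spacing": list(geom.pixel_spacing),
            "slice_thickness": geom.slice_thickness,
            "phases": sorted(geom.masks)}
    (outdir / "geometry.json").write_text(json.dumps(meta, indent=2))


def load_lv_geometry(cine_dir) -> lvf.LVGeometry:
    cine_dir = Path(cine_dir)
    meta = json.loads((cine_dir / "geometry.json").read_text())
    for key in ("pixel_spacing", "slice_thickness", "phases"):
        if key not in meta:
            raise SchemaError(f"geometry sidecar missing field {key!r}")
    masks = {p: (load_mask(cine_dir / f"{p}_endo.nii"),
                 load_mask(cine_dir / f"{p}_epi.nii"))
             for p in meta["phases"]}
    return lvf.LVGeometry(masks=masks,
                          pixel_spacing=tuple(meta["pixel_spacing"]),
                          slice_thickness=meta["slice_thickness"])


def analyze_cine_dir(cine_dir) -> lvf.LVIndices:
    return lvf.lv_indices(load_lv_geometry(cine_dir))


def _write_strain(outdir: Path, frames: strain_mod.StrainFrameSet) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pts = pd.DataFrame({"x_mm": frames.points[:, 0],
                        "y_mm": frames.points[:, 1],
                        "depth": frames.depth})
    write_table(pts, outdir / "points.csv")
    nf, npts, _ = frames.displacements.shape
    f_idx, p_idx = np.meshgrid(np.arange(nf), np.arange(npts), indexing="ij")
    disp = pd.DataFrame({
        "frame": f_idx.ravel(), "point": p_idx.ravel(),
        "ux_mm": frames.displacements[..., 0].ravel(),
        "uy_mm": frames.displacements[..., 1].ravel()})
    write_table(disp, outdir / "displacements.csv")
    meta = {"center": list(map(float, frames.center)),
            "frame_times": [float(x) for x in frames.frame_times]}
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2))


def load_strain_frameset(strain_dir) -> strain_mod.StrainFrameSet:
    strain_dir = Path(strain_dir)
    meta = json.loads((strain_dir / "meta.json").read_text())
    pts = read_table(strain_dir / "points.csv")
    disp = read_table(strain_dir / "displacements.csv")
    nf = len(meta["frame_times"])
    npts = len(pts)
    u = np.zeros((nf, npts, 2))
    u[disp["frame"], disp["point"], 0] = disp["ux_mm"]
    u[disp["frame"], disp["point"], 1] = disp["uy_mm"]
    return strain_mod.StrainFrameSet(
        points=pts[["x_mm", "y_mm"]].to_numpy(),
        displacements=u, center=np.asarray(meta["center"], float),
        frame_times=np.asarray(meta["frame_times"], float),
        depth=pts["depth"].to_numpy())


def analyze_strain_dir(strain_dir, n_sectors: int = 24) -> dict[str, float]:
    frames = load_strain_frameset(strain_dir)
    profile = strain_mod.ecc_profiles(frames, n_sectors=n_sectors)
    peaks = strain_mod.peak_global_ecc(profile)
    cure = strain_mod.compute_cure(profile.segmental)
    return {"ecc_global": peaks["global"], "ecc_subendo": peaks["subendo"],
            "ecc_subepi": peaks["subepi"], "cure": cure.cure}


def analyze_gtt_file(path, subject: str = "", group: str = "",
                     week: int | None = None) -> dict[str, float]:
    df = read_table(path)
    for col in ("time_min", "glucose_mg_dl"):
        if col not in df.columns:
            raise SchemaError(f"GTT table missing column {col!r}")
    rec = gtt_mod.GTTRecord(times=df["time_min"].to_numpy(),
                            glucose=df["glucose_mg_dl"].to_numpy(),
                            subject=subject, group=group, week=week)
    return {"gtt_auc": gtt_mod.auc_trapezoid(rec),
            "fasting_glucose": gtt_mod.fasting_glucose(rec)}


# ---------------------------------------------------------------------------
# Study input generation (phantom cohort → files + manifest)
# ---------------------------------------------------------------------------

#: Glucose profiles per group × week: HFD mice become hyperglycemic and
#: glucose-intolerant from 12 weeks on, controls stay stable.
DEFAULT_GTT_PROFILES = {
    "control": {wk: synth.GTTProfile(92.0, 170.0, 20.0) for wk in (6, 12, 18, 24)},
    "hfd": {6: synth.GTTProfile(100.0, 200.0, 22.0),
            12: synth.GTTProfile(125.0, 300.0, 30.0),
            18: synth.GTTProfile(130.0, 320.0, 30.0),
            24: synth.GTTProfile(128.0, 330.0, 30.0)},
}

_EDV_UL = 43.0          # µL, end-diastolic cavity volume of the phantom LV
_N_SLICES = 6
_SLICE_THICKNESS = 1.0  # mm


def _lv_geometry_for(mass_mg: float, ef_pct: float):
    """Annular-cylinder ED/ES radii realizing a target mass and EF."""
    ef_pct = float(np.clip(ef_pct, 5.0, 95.0))
    r_endo_ed = np.sqrt(_EDV_UL / (_N_SLICES * np.pi * _SLICE_THICKNESS))
    myo_area = mass_mg / (1.05 * _N_SLICES * _SLICE_THICKNESS)
    r_epi_ed = np.sqrt(r_endo_ed ** 2 + myo_area / np.pi)
    r_endo_es = r_endo_ed * np.sqrt(1.0 - ef_pct / 100.0)
    r_epi_es = synth.incompressible_epi_radius(r_epi_ed, r_endo_ed, r_endo_es)
    return {"ED": (r_endo_ed, r_epi_ed), "ES": (r_endo_es, r_epi_es)}


def write_study_inputs(config: synth.CohortConfig, outdir,
                       noise_sd: float = 0.002,
                       gtt_noise_sd: float = 8.0) -> Path:
    """Render the full file tree of a synthetic two-arm longitudinal study.

    Per-subject ground truth is drawn by :func:`synthetic.generate_cohort`
    (MPR, LV mass, EF, Ecc, body weight per week); each subject × week gets
    rendered perfusion stacks (rest at 4 mL/min/g, stress at rest × drawn
    MPR), cine mask stacks, cylinder displacement fields and a GTT table.
    Everything derives deterministically from ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = synth.generate_cohort(config)
    write_table(cohort, outdir / "subjects.csv")

    acq = AcquisitionParams()
    subjects: list[dict] = []
    for si, (subject, sub_rows) in enumerate(cohort.groupby("subject", sort=True)):
        group = sub_rows["group"].iloc[0]
        weeks_entry: dict[str, dict[str, str]] = {}
        for wi, wk in enumerate(config.timepoints):
            row = sub_rows[sub_rows["week"] == wk].iloc[0]
            rel = Path(f"sub-{subject}") / f"wk{wk:02d}"
            base = outdir / rel
            ss = np.random.SeedSequence(entropy=config.seed,
                                        spawn_key=(si, wi))
            seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                     for s in ss.spawn(2)]

            mpr_true = max(float(row["mpr"]), 1.0)
            phantom = synth.PhantomGroundTruth(
                mbf_rest=4.0, mbf_stress=4.0 * mpr_true,
                noise_sd=noise_sd, seed=seeds[0])
            rendered = synth.render_perfusion_series(phantom, acq)
            for cond, data in rendered.conditions.items():
                _write_perfusion_condition(base / "perfusion" / cond, data, acq)

            geom, _ = synth.render_lv_masks(
                _lv_geometry_for(float(row["lv_mass"]), float(row["ef"])),
                n_slices=_N_SLICES, pixel_spacing=(0.15, 0.15),
                slice_thickness=_SLICE_THICKNESS, image_shape=(96, 96))
            _write_cine(base / "cine", geom)

            ecc_target = float(np.clip(row.get("ecc", -0.13), -0.45, -0.01))
            deform = synth.solve_peak_ecc(ecc_target, spacing=0.25)
            frames, _ = synth.render_displacements(deform, spacing=0.25,
                                                   n_frames=6)
            _write_strain(base / "strain", frames)

            profile = DEFAULT_GTT_PROFILES[group][wk] \
                if wk in DEFAULT_GTT_PROFILES.get(group, {}) \
                else synth.GTTProfile()
            rec, _ = synth.generate_gtt(profile, noise_sd=gtt_noise_sd,
                                        seed=seeds[1], subject=subject,
                                        group=group, week=int(wk))
            write_table(pd.DataFrame({"time_min": rec.times,
                                      "glucose_mg_dl": rec.glucose}),
                        base / "gtt.csv")

            weeks_entry[str(int(wk))] = {
                "perfusion_rest": str(rel / "perfusion" / "rest"),
                "perfusion_stress": str(rel / "perfusion" / "stress"),
                "cine": str(rel / "cine"),
                "strain": str(rel / "strain"),
                "gtt": str(rel / "gtt.csv"),
                "body_weight": float(row["body_weight"]),
            }
        subjects.append({"id": subject, "group": group, "weeks": weeks_entry})

    manifest = {"timepoints": [int(w) for w in config.timepoints],
                "subjects": subjects}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


# ---------------------------------------------------------------------------
# Study orchestration
# ---------------------------------------------------------------------------

def _metrics_for(manifest_root: Path, entry: dict, subject: str,
                 group: str, week: int) -> dict[str, float]:
    """All metrics for one subject × week; missing/broken modalities yield
    missing cells with a log entry, never an aborted run."""
    out: dict[str, float] = {}

    def _try(label, fn):
        try:
            out.update(fn())
        except FileNotFoundError as e:
            logger.warning("%s wk%s %s: input missing (%s); cell left empty",
                           subject, week, label, e)
        except Exception as e:
            logger.warning("%s wk%s %s: failed (%s); cell left empty",
                           subject, week, label, e)

    def _perfusion():
        # analyse conditions independently so a broken stress scan only
        # blanks the stress/MPR cells, not the rest measurement
        results = {}
        for cond in ("rest", "stress"):
            try:
                results[cond] = analyze_perfusion_dir(
                    manifest_root / entry[f"perfusion_{cond}"], condition=cond)
                out[f"mbf_{cond}"] = results[cond].mbf
            except Exception as e:
                logger.warning("%s wk%s perfusion %s: failed (%s); cell left "
                               "empty", subject, week, cond, e)
        if len(results) == 2 and not any(r.flagged for r in results.values()):
            return {"mpr": perf.compute_mpr(results["rest"],
                                            results["stress"]).mpr}
        return {}

    def _cine():
        idx = analyze_cine_dir(manifest_root / entry["cine"])
        return {"edv": idx.edv, "esv": idx.esv, "ef": idx.ef,
                "lv_mass": idx.mass, "edwt": idx.edwt, "eswt": idx.eswt}

    if "perfusion_rest" in entry and "perfusion_stress" in entry:
        _try("perfusion", _perfusion)
    if "cine" in entry:
        _try("cine", _cine)
    if "strain" in entry:
        _try("strain", lambda: analyze_strain_dir(manifest_root / entry["strain"]))
    if "gtt" in entry:
        _try("gtt", lambda: analyze_gtt_file(manifest_root / entry["gtt"],
                                             subject, group, week))
    if "body_weight" in entry:
        out["body_weight"] = float(entry["body_weight"])
    return out


def run_study(manifest: StudyManifest | str | Path,
              out_dir=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run every stage for every subject × timepoint and summarise by group.

    Returns (per-subject long table, group summary).  The long table has one
    row per subject × week × metric; the summary reports mean, SD and n per
    group × week × metric, with SD missing when n = 1.  If ``out_dir`` is
    given, ``per_subject.csv`` and ``summary.csv`` are written there.
    """
    if not isinstance(manifest, StudyManifest):
        manifest = read_manifest(manifest)
    digest = hashlib.sha256(
        json.dumps([manifest.timepoints, manifest.subjects],
                   sort_keys=True).encode()).hexdigest()[:12]
    logger.info("run_study: %d subjects, weeks %s, manifest hash %s",
                len(manifest.subjects), manifest.timepoints, digest)

    rows = []
    for sub in manifest.subjects:
        for wk_key, entry in sorted(sub["weeks"].items(), key=lambda kv: int(kv[0])):
            week = int(wk_key)
            metrics = _metrics_for(manifest.root, entry, sub["id"],
                                   sub["group"], week)
            for metric, value in sorted(metrics.items()):
                rows.append({"subject": sub["id"], "group": sub["group"],
                             "week": week, "metric": metric, "value": value})
    per_subject = pd.DataFrame(rows)

    grouped = per_subject.groupby(["group", "week", "metric"])["value"]
    summary = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    summary.loc[summary["n"] <= 1, "sd"] = np.nan

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_table(per_subject, out_dir / "per_subject.csv")
        write_table(summary, out_dir / "summary.csv")
    return per_subject, summary
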