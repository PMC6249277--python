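"""Synthetic longitudinal paired-eye cohorts for structure-function analysis.

The generator emulates a glaucoma progression cohort: ~100 patients, a
subset contributing both eyes, four-plus paired visual-field / OCT visits
per eye over several years, global RNFL thickness around 68 um and mean
deviation around -6 dB at entry, and slow negative slopes in both
modalities.

Generative model
----------------
Per eye, latent baselines and slopes are drawn hierarchically: each latent
is a subject-level plus an eye-level Gaussian component, with
``between_eye_variance_fraction`` of the variance at the eye level.
Structural and functional latents are correlated with
``sf_slope_correlation`` at both levels, so the total per-eye
structure-function latent correlation equals the configured value.

Structure.  A smooth double-hump TSNIT base curve (first two circular
harmonics, frozen coefficients) is scaled by the eye's baseline global
thickness; thickness declines linearly in time with the eye's structural
slope, uniformly around the circle.  Optional wedge-shaped nerve-fiber-layer
defects (angular notches that deepen/widen linearly in time) can be
superimposed.  Observation noise is one Gaussian draw per visit per
standard 6-sector arc, shared by the samples of the arc, so any sector mean
carries noise of the configured standard deviation.

Function.  At baseline, each field sector's sensitivity is linked to the
corresponding disc sector's thickness on the linear (1/Lambert) scale:
``1/L = a * max(T - b, 0)`` with gain ``a`` and thickness floor ``b``
(roughly the glial/vascular remnant below which perimetric sensitivity is
extinguished).  A per-eye offset on the dB scale calibrates the implied
mean deviation to the eye's drawn baseline MD, preserving the
structure-function coupling while honouring the configured MD moments.
Sensitivity then declines linearly in dB at the eye's functional slope;
per-point Gaussian noise is added on the dB scale and negative
sensitivities are clamped to 0 dB.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .datatypes import CpRNFLProfile, N_PROFILE_SAMPLES, VisualFieldExam
from .errors import ValidationError
from .grids import GRID_24_2
from .sector_maps import (GLOBAL, SectorMap, assign_samples,
                          denormalize_laterality, get_map, sample_angles)

#: Frozen circular-harmonic coefficients of the TSNIT base curve
#: h(theta) = 1 + c1*cos + c2*sin + c3*cos2 + c4*sin2 (canonical frame).
#: Calibrated so the six standard sector means reproduce the relative
#: thickness pattern of a moderate glaucoma cohort (temporal-superior and
#: temporal-inferior humps, thin nasal trough).
TSNIT_COEF = (0.09787464, 0.08319876, -0.24667231, 0.05902992)

#: Flat age-normal sensitivity (dB) used as the total-deviation reference.
NORMAL_SENSITIVITY_DB = 30.0


def tsnit_shape(angles_deg: np.ndarray) -> np.ndarray:
    """Unit-mean TSNIT base curve evaluated at the given angles."""
    r = np.deg2rad(angles_deg)
    c1, c2, c3, c4 = TSNIT_COEF
    return 1.0 + c1 * np.cos(r) + c2 * np.sin(r) + c3 * np.cos(2 * r) + c4 * np.sin(2 * r)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults emulate the study-scale cohort."""

    n_subjects: int = 100
    bilateral_fraction: float = 0.31
    followup_years_mean: float = 3.68
    followup_years_sd: float = 0.95
    visit_interval_mean: float = 0.5
    visit_interval_sd: float = 0.15
    baseline_md_mean: float = -6.20
    baseline_md_sd: float = 4.34
    baseline_rnflt_mean: float = 68.5
    baseline_rnflt_sd: float = 11.6
    slope_md_mean: float = -0.30
    slope_md_sd: float = 0.40
    slope_rnflt_mean: float = -0.95
    slope_rnflt_sd: float = 1.00
    # focal (per-sector) slope heterogeneity around the eye's overall rate;
    # corresponding structural/functional sector deviations share the same
    # latent correlation, emulating focal progression (wedge defects and
    # their field counterparts) rather than uniform thinning
    slope_rnflt_sector_sd: float = 0.50
    slope_md_sector_sd: float = 0.15
    between_eye_variance_fraction: float = 0.3
    sf_slope_correlation: float = 0.6
    link_gain_a: float = 6.5       # (1/L) per um above the floor
    link_floor_b: float = 30.0     # um; residual glial/vascular thickness
    vf_point_noise_sd: float = 1.8  # dB, per point per visit
    oct_sector_noise_sd: float = 2.0  # um, per sector per visit
    fovea_onh_angle_mean: float = -7.63
    fovea_onh_angle_sd: float = 4.04
    # optional wedge defects (off by default so sector trajectories stay
    # exactly linear in time)
    nfld_fraction: float = 0.0
    nfld_depth_um: float = 15.0
    nfld_width_deg: float = 20.0
    nfld_deepen_um_per_year: float = 0.0
    nfld_widen_deg_per_year: float = 0.0
    link_map: str = "garway_heath"
    seed: int = 0

    def __post_init__(self):
        for name in ("followup_years_sd", "visit_interval_sd", "baseline_md_sd",
                     "baseline_rnflt_sd", "slope_md_sd", "slope_rnflt_sd",
                     "slope_rnflt_sector_sd", "slope_md_sector_sd",
                     "vf_point_noise_sd", "oct_sector_noise_sd",
                     "fovea_onh_angle_sd", "nfld_depth_um", "nfld_width_deg"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValidationError(f"{name}={v} must be finite and >= 0")
        for name in ("bilateral_fraction", "between_eye_variance_fraction",
                     "nfld_fraction"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} must lie in [0, 1]")
        if not np.isfinite(self.sf_slope_correlation) or abs(self.sf_slope_correlation) > 1:
            raise ValidationError("sf_slope_correlation must lie in [-1, 1]")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if not np.isfinite(self.link_gain_a) or self.link_gain_a <= 0:
            raise ValidationError("link_gain_a must be positive")
        if not np.isfinite(self.link_floor_b) or self.link_floor_b < 0:
            raise ValidationError("link_floor_b must be >= 0")
        for name in ("followup_years_mean", "visit_interval_mean",
                     "baseline_md_mean", "baseline_rnflt_mean",
                     "slope_md_mean", "slope_rnflt_mean",
                     "fovea_onh_angle_mean"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")
        if self.visit_interval_mean <= 0:
            raise ValidationError("visit_interval_mean must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class EyeTruth:
    """Latent (noise-free) generating quantities for one eye.

    Structural truths are in um (intercept and slope of each disc-sector
    mean); functional truths are in dB (intercept and slope of each field
    sector's sensitivity).  ``func_thickness_um`` is the latent functional
    thickness at baseline per disc sector: the thickness whose linear-scale
    link reproduces the baseline sensitivity exactly.
    """

    eye_id: str
    subject_id: str
    laterality: str
    fovea_onh_angle_deg: float
    struct_intercept_um: dict   # per disc sector + 'global', um
    struct_slope_um_per_year: dict
    func_intercept_db: dict     # per field sector + 'global', dB
    func_slope_db_per_year: dict
    func_thickness_um: dict     # per field sector, um (latent link inverse)
    baseline_md_db: float


@dataclass(frozen=True)
class Visit:
    eye_id: str
    time_years: float
    exam: VisualFieldExam
    profile: CpRNFLProfile


@dataclass(frozen=True)
class Cohort:
    config: SynthConfig
    subjects: tuple
    eyes: tuple      # EyeTruth records
    visits: tuple    # Visit records, grouped by eye, times increasing

    def eye_visits(self, eye_id: str):
        return [v for v in self.visits if v.eye_id == eye_id]


def _corr_pair(rng: np.random.Generator, rho: float, size) -> tuple:
    """Two standard-normal vectors with correlation rho."""
    z1 = rng.standard_normal(size)
    z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho ** 2)) * rng.standard_normal(size)
    return z1, z2


def _hier_latent(rng, rho, kappa, n_subjects, eye_subject_index):
    """Per-eye correlated latent pairs with subject/eye variance split."""
    zs_s, zs_f = _corr_pair(rng, rho, n_subjects)
    n_eyes = len(eye_subject_index)
    ze_s, ze_f = _corr_pair(rng, rho, n_eyes)
    w_sub, w_eye = np.sqrt(1.0 - kappa), np.sqrt(kappa)
    u_s = w_sub * zs_s[eye_subject_index] + w_eye * ze_s
    u_f = w_sub * zs_f[eye_subject_index] + w_eye * ze_f
    return u_s, u_f


def _visit_times(rng, cfg: SynthConfig) -> np.ndarray:
    horizon = max(1.5, rng.normal(cfg.followup_years_mean, cfg.followup_years_sd))
    times = [0.0]
    while times[-1] < horizon:
        gap = max(0.1, rng.normal(cfg.visit_interval_mean, cfg.visit_interval_sd))
        times.append(times[-1] + gap)
    while len(times) < 4:  # the >=4-exam inclusion rule, by construction
        times.append(times[-1] + max(0.1, rng.normal(cfg.visit_interval_mean,
                                                     cfg.visit_interval_sd)))
    return np.asarray(times)


def _link_db(thickness_um, a, b):
    """Baseline link: sensitivity in dB of 1/L = a*max(T-b, eps)."""
    lin = a * np.maximum(np.asarray(thickness_um, dtype=float) - b, 1e-6)
    return 10.0 * np.log10(lin)


def _calibrate_offset(sector_db_uncal: np.ndarray, weights: np.ndarray,
                      target_md: float) -> float:
    """Per-eye dB offset making the implied mean deviation hit target_md.

    The implied MD is the point-weighted mean of sector sensitivities minus
    the flat normal reference; the offset is additive in dB, so the solution
    is closed-form.
    """
    implied = float(np.average(sector_db_uncal, weights=weights))
    return target_md + NORMAL_SENSITIVITY_DB - implied


def generate_cohort(config: SynthConfig) -> Cohort:
    """Generate a deterministic synthetic cohort from ``config``.

    Identical configurations (including ``seed``) produce identical
    cohorts.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    link_map = get_map(cfg.link_map)

    # eyes per subject and lateralities
    eye_subject_index, lateralities, subjects = [], [], []
    for j in range(cfg.n_subjects):
        sid = f"S{j:04d}"
        subjects.append(sid)
        bilateral = rng.random() < cfg.bilateral_fraction
        if bilateral:
            sides = ["OD", "OS"]
        else:
            sides = ["OD" if rng.random() < 0.5 else "OS"]
        for side in sides:
            eye_subject_index.append(j)
            lateralities.append(side)
    eye_subject_index = np.asarray(eye_subject_index)
    n_eyes = len(eye_subject_index)
    kappa = cfg.between_eye_variance_fraction
    rho = cfg.sf_slope_correlation

    ub_s, ub_f = _hier_latent(rng, rho, kappa, cfg.n_subjects, eye_subject_index)
    us_s, us_f = _hier_latent(rng, rho, kappa, cfg.n_subjects, eye_subject_index)
    base_rnflt = cfg.baseline_rnflt_mean + cfg.baseline_rnflt_sd * ub_s
    base_md = cfg.baseline_md_mean + cfg.baseline_md_sd * ub_f
    slope_rnflt = cfg.slope_rnflt_mean + cfg.slope_rnflt_sd * us_s
    slope_md = cfg.slope_md_mean + cfg.slope_md_sd * us_f
    base_rnflt = np.maximum(base_rnflt, cfg.link_floor_b + 2.0)  # keep above floor
    angles_fonh = rng.normal(cfg.fovea_onh_angle_mean, cfg.fovea_onh_angle_sd, n_eyes)

    # geometry shared by all eyes
    angles = sample_angles()
    shape = tsnit_shape(angles)
    noise_arcs = get_map("spectralis6").disc_sectors
    noise_idx = assign_samples(noise_arcs)
    n_arcs = len(noise_arcs)
    link_idx = assign_samples(link_map.disc_sectors)
    disc_labels = link_map.disc_labels
    field_labels = link_map.vf_labels
    # field sector s <-> disc sector corr(s); per-point field-sector index
    corr_disc_index = np.array([disc_labels.index(link_map.correspondence[s])
                                for s in field_labels])
    point_field = np.array([field_labels.index(link_map.vf_assignment[p])
                            for p in GRID_24_2])
    field_weights = np.bincount(point_field,
                                minlength=len(field_labels)).astype(float)
    arc_weights = np.bincount(link_idx, minlength=len(disc_labels)).astype(float)
    arc_weights /= arc_weights.sum()

    eyes, visits = [], []
    for e in range(n_eyes):
        j = eye_subject_index[e]
        sid = subjects[j]
        side = lateralities[e]
        eye_id = f"{sid}_{side}"
        # structural truth
        prof0 = base_rnflt[e] * shape
        struct_sector0 = {GLOBAL: float(prof0.mean())}
        for i, lab in enumerate(disc_labels):
            struct_sector0[lab] = float(prof0[link_idx == i].mean())
        # per-sector slope deviations, correlated across modalities within
        # corresponding pairs (focal progression)
        zd, zf = _corr_pair(rng, rho, len(field_labels))
        sector_slope_disc = np.full(len(disc_labels), slope_rnflt[e])
        sector_slope_disc[corr_disc_index] += cfg.slope_rnflt_sector_sd * zd
        sample_slope = sector_slope_disc[link_idx]
        struct_slope = {GLOBAL: float(sample_slope.mean())}
        for i, lab in enumerate(disc_labels):
            struct_slope[lab] = float(sector_slope_disc[i])
        # functional truth via the linear-scale link, calibrated to baseline MD
        field_T0 = np.array([struct_sector0[disc_labels[d]]
                             for d in corr_disc_index])
        db_uncal = _link_db(field_T0, cfg.link_gain_a, cfg.link_floor_b)
        offset = _calibrate_offset(db_uncal, field_weights, base_md[e])
        field_db0 = db_uncal + offset
        field_slope = slope_md[e] + cfg.slope_md_sector_sd * zf
        func_int = {s: float(field_db0[i]) for i, s in enumerate(field_labels)}
        func_int[GLOBAL] = float(np.average(field_db0, weights=field_weights))
        func_slope = {s: float(field_slope[i]) for i, s in enumerate(field_labels)}
        func_slope[GLOBAL] = float(np.average(field_slope,
                                              weights=field_weights))
        # latent functional thickness: inverse link of the calibrated dB
        func_T = {s: float(10.0 ** (field_db0[i] / 10.0) / cfg.link_gain_a
                           + cfg.link_floor_b)
                  for i, s in enumerate(field_labels)}

        # optional wedge defect
        has_nfld = rng.random() < cfg.nfld_fraction
        nfld_center = float(rng.choice([70.0, 290.0]) + rng.normal(0, 10))
        truth = EyeTruth(
            eye_id=eye_id, subject_id=sid, laterality=side,
            fovea_onh_angle_deg=float(angles_fonh[e]),
            struct_intercept_um=struct_sector0,
            struct_slope_um_per_year=struct_slope,
            func_intercept_db=func_int,
            func_slope_db_per_year=func_slope,
            func_thickness_um=func_T,
            baseline_md_db=float(base_md[e]))
        eyes.append(truth)

        times = _visit_times(rng, cfg)
        for t in times:
            prof_t = prof0 + sample_slope * t
            if has_nfld:
                depth = cfg.nfld_depth_um + cfg.nfld_deepen_um_per_year * t
                width = cfg.nfld_width_deg + cfg.nfld_widen_deg_per_year * t
                d = np.abs((angles - nfld_center + 180) % 360 - 180)
                prof_t = prof_t - depth * np.exp(-0.5 * (d / (width / 2.355)) ** 2)
            if cfg.oct_sector_noise_sd > 0:
                arc_noise = rng.normal(0, cfg.oct_sector_noise_sd, n_arcs)
                prof_t = prof_t + arc_noise[noise_idx]
            prof_t = np.clip(prof_t, 1.0, 299.0)
            profile = CpRNFLProfile(
                eye_id=eye_id, subject_id=sid, laterality="OD",
                time_years=float(t), thickness_um=tuple(prof_t),
                fovea_onh_angle_deg=float(angles_fonh[e]))
            profile = denormalize_laterality(profile, side)

            point_db = field_db0[point_field] + field_slope[point_field] * t
            if cfg.vf_point_noise_sd > 0:
                point_db = point_db + rng.normal(0, cfg.vf_point_noise_sd,
                                                 len(GRID_24_2))
            point_db = np.maximum(point_db, 0.0)
            td = point_db - NORMAL_SENSITIVITY_DB
            pts = {p: (float(point_db[i]), float(td[i]))
                   for i, p in enumerate(GRID_24_2)}
            md = float(td.mean())
            psd = float(td.std(ddof=1))
            exam = VisualFieldExam(
                eye_id=eye_id, subject_id=sid, laterality="OD",
                time_years=float(t), points=pts, md_dB=md, psd_dB=psd,
                fixation_loss=float(rng.uniform(0, 0.15)),
                false_pos=float(rng.uniform(0, 0.10)),
                false_neg=float(rng.uniform(0, 0.15)))
            if side == "OS":
                exam = denormalize_laterality(exam, "OS")
            visits.append(Visit(eye_id=eye_id, time_years=float(t),
                                exam=exam, profile=profile))

    return Cohort(config=cfg, subjects=tuple(subjects), eyes=tuple(eyes),
                  visits=tuple(visits))


# ---------------------------------------------------------------------------
# serialization

def write_cohort(cohort: Cohort, directory) -> dict:
    """Write a cohort to ``directory`` as three CSV tables plus a YAML dump
    of the generating configuration.

    Files: ``vf.csv`` (one row per exam), ``oct.csv`` (one row per scan),
    ``eyes.csv`` (one row per eye, latent truths), ``synth_config.yaml``.
    Returns a manifest of paths and row counts.
    """
    from .io import write_oct_table, write_vf_table  # deferred: io imports datatypes

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    exams = [v.exam for v in cohort.visits]
    profiles = [v.profile for v in cohort.visits]
    vf_path = directory / "vf.csv"
    oct_path = directory / "oct.csv"
    write_vf_table(exams, vf_path)
    write_oct_table(profiles, oct_path)

    import pandas as pd
    eye_rows = []
    for t in cohort.eyes:
        row = {"eye_id": t.eye_id, "subject_id": t.subject_id,
               "laterality": t.laterality,
               "fovea_onh_angle_deg": t.fovea_onh_angle_deg,
               "baseline_md_db": t.baseline_md_db}
        for lab, v in t.struct_intercept_um.items():
            row[f"struct0_{lab}"] = v
        for lab, v in t.struct_slope_um_per_year.items():
            row[f"struct_slope_{lab}"] = v
        for lab, v in t.func_intercept_db.items():
            row[f"func0_{lab}"] = v
        for lab, v in t.func_slope_db_per_year.items():
            row[f"func_slope_{lab}"] = v
        for lab, v in t.func_thickness_um.items():
            row[f"funcT_{lab}"] = v
        eye_rows.append(row)
    eyes_path = directory / "eyes.csv"
    pd.DataFrame(eye_rows).to_csv(eyes_path, index=False)

    cfg_path = directory / "synth_config.yaml"
    with open(cfg_path, "w") as f:
        yaml.safe_dump(cohort.config.to_dict(), f, sort_keys=True)

    manifest = {
        "vf": {"path": str(vf_path), "rows": len(exams)},
        "oct": {"path": str(oct_path), "rows": len(profiles)},
        "eyes": {"path": str(eyes_path), "rows": len(cohort.eyes)},
        "config": {"path": str(cfg_path)},
    }
    return manifest
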