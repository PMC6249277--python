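"""CSV readers/writers for visual-field and OCT long-format tables.

Schemas (UTF-8, comma-separated, header row, ``.`` decimal, times in
decimal years, laterality OD/OS):

Visual field
    ``subject_id, eye_id, laterality, time_years, fixation_loss, false_pos,
    false_neg, md_dB, psd_dB`` then 52 paired columns ``thr_<x>_<y>`` and
    ``td_<x>_<y>`` with signed field degrees, always in the OD frame
    (left-eye exams are mirrored on write and restored to their own frame
    on read using the ``laterality`` column).

OCT
    ``subject_id, eye_id, laterality, time_years, fovea_onh_angle_deg``
    then ``t_000 ... t_767`` (um).  1536-column input (``t_0000...t_1535``)
    is accepted and resampled to 768 by adjacent-pair averaging.

Reading applies the standard reliability rule to visual-field rows
(fixation loss < 20%, false-negative < 33%, false-positive threshold
configurable, default < 33%) and drops eyes left with fewer than four
exams, logging counts for the exclusion ledger.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CpRNFLProfile, N_PROFILE_SAMPLES, VisualFieldExam
from .errors import SchemaError, ValidationError
from .grids import GRID_24_2, point_key

logger = logging.getLogger(__name__)

VF_META_COLS = ["subject_id", "eye_id", "laterality", "time_years",
                "fixation_loss", "false_pos", "false_neg", "md_dB", "psd_dB"]
OCT_META_COLS = ["subject_id", "eye_id", "laterality", "time_years",
                 "fovea_onh_angle_deg"]

THR_COLS = [f"thr_{point_key(x, y)}" for x, y in GRID_24_2]
TD_COLS = [f"td_{point_key(x, y)}" for x, y in GRID_24_2]
T_COLS_768 = [f"t_{k:03d}" for k in range(N_PROFILE_SAMPLES)]
T_COLS_1536 = [f"t_{k:04d}" for k in range(2 * N_PROFILE_SAMPLES)]


# ---------------------------------------------------------------------------
# writers

def write_vf_table(exams, path) -> None:
    rows = []
    for ex in exams:
        # per-point columns are always written in the OD frame
        from .sector_maps import normalize_laterality
        exn = normalize_laterality(ex)
        row = {"subject_id": ex.subject_id, "eye_id": ex.eye_id,
               "laterality": ex.laterality, "time_years": ex.time_years,
               "fixation_loss": ex.fixation_loss, "false_pos": ex.false_pos,
               "false_neg": ex.false_neg, "md_dB": ex.md_dB, "psd_dB": ex.psd_dB}
        for (x, y) in GRID_24_2:
            thr, td = exn.points[(x, y)]
            row[f"thr_{point_key(x, y)}"] = thr
            row[f"td_{point_key(x, y)}"] = td
        rows.append(row)
    cols = VF_META_COLS + [c for pair in zip(THR_COLS, TD_COLS) for c in pair]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_oct_table(profiles, path) -> None:
    rows = []
    for pr in profiles:
        row = {"subject_id": pr.subject_id, "eye_id": pr.eye_id,
               "laterality": pr.laterality, "time_years": pr.time_years,
               "fovea_onh_angle_deg": pr.fovea_onh_angle_deg}
        for k, v in enumerate(pr.thickness_um):
            row[f"t_{k:03d}"] = v
        rows.append(row)
    pd.DataFrame(rows, columns=OCT_META_COLS + T_COLS_768).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# readers

def _check_monotone_times(df: pd.DataFrame, what: str) -> None:
    for eye, g in df.groupby("eye_id", sort=False):
        t = g["time_years"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"{what}: times for eye {eye!r} are not strictly increasing")


def read_vf_table(path, fl_max: float = 0.20, fp_max: float = 1.0 / 3.0,
                  fn_max: float = 1.0 / 3.0, min_exams: int = 4,
                  drop_first_lifetime: bool = False) -> tuple:
    """Parse a visual-field CSV into exams, applying reliability exclusion.

    Returns ``(exams, stats)`` where ``stats`` records
    ``rows_in / rows_used / rows_excluded_unreliable / eyes_dropped`` and,
    when the optional ``is_first_lifetime_test`` column is present and
    ``drop_first_lifetime`` is set, the count of first-lifetime tests
    removed (perimetric learning-effect convention).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in VF_META_COLS + THR_COLS + TD_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"visual-field table lacks columns: {missing[:5]} ...")
    stats = {"rows_in": len(df), "rows_excluded_unreliable": 0,
             "rows_excluded_first_lifetime": 0, "eyes_dropped": 0,
             "rows_used": 0}
    if drop_first_lifetime and "is_first_lifetime_test" in df.columns:
        first = df["is_first_lifetime_test"].astype(bool)
        stats["rows_excluded_first_lifetime"] = int(first.sum())
        df = df[~first]
    reliable = ((df["fixation_loss"] < fl_max)
                & (df["false_pos"] < fp_max)
                & (df["false_neg"] < fn_max))
    stats["rows_excluded_unreliable"] = int((~reliable).sum())
    if stats["rows_excluded_unreliable"]:
        logger.info("excluded %d unreliable visual-field row(s)",
                    stats["rows_excluded_unreliable"])
    df = df[reliable]
    counts = df.groupby("eye_id")["time_years"].count()
    keep_eyes = set(counts[counts >= min_exams].index)
    dropped = sorted(set(counts.index) - keep_eyes)
    stats["eyes_dropped"] = len(dropped)
    if dropped:
        logger.info("dropped %d eye(s) with fewer than %d reliable exams: %s",
                    len(dropped), min_exams, dropped)
    df = df[df["eye_id"].isin(keep_eyes)]
    df = df.sort_values(["eye_id", "time_years"], kind="mergesort")
    _check_monotone_times(df, "visual-field table")

    exams = []
    thr = df[THR_COLS].to_numpy(dtype=float)
    td = df[TD_COLS].to_numpy(dtype=float)
    for i, (_, r) in enumerate(df.iterrows()):
        pts = {p: (thr[i, k], td[i, k]) for k, p in enumerate(GRID_24_2)}
        lat = str(r["laterality"])
        ex = VisualFieldExam(
            eye_id=str(r["eye_id"]), subject_id=str(r["subject_id"]),
            laterality="OD", time_years=float(r["time_years"]), points=pts,
            md_dB=float(r["md_dB"]), psd_dB=float(r["psd_dB"]),
            fixation_loss=float(r["fixation_loss"]),
            false_pos=float(r["false_pos"]), false_neg=float(r["false_neg"]))
        if lat == "OS":
            from .sector_maps import denormalize_laterality
            ex = denormalize_laterality(ex, "OS")
        exams.append(ex)
    stats["rows_used"] = len(exams)
    stats["rows_excluded_few_exams"] = (
        stats["rows_in"] - stats["rows_used"]
        - stats["rows_excluded_unreliable"]
        - stats["rows_excluded_first_lifetime"])
    return exams, stats


def read_oct_table(path, min_exams: int = 4) -> tuple:
    """Parse an OCT CSV into profiles; accepts 768- or 1536-sample rows.

    1536-sample rows are resampled to 768 by adjacent-pair averaging.
    Returns ``(profiles, stats)``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in OCT_META_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"OCT table lacks columns: {missing}")
    if all(c in df.columns for c in T_COLS_768):
        thick = df[T_COLS_768].to_numpy(dtype=float)
    elif all(c in df.columns for c in T_COLS_1536):
        raw = df[T_COLS_1536].to_numpy(dtype=float)
        thick = 0.5 * (raw[:, 0::2] + raw[:, 1::2])
    else:
        n_t = sum(c.startswith("t_") for c in df.columns)
        raise SchemaError(
            f"OCT table must carry exactly 768 (t_000..t_767) or 1536 "
            f"(t_0000..t_1535) thickness columns; found {n_t}")
    if np.any(thick < 0):
        raise ValidationError("negative thickness values in OCT table")
    stats = {"rows_in": len(df), "eyes_dropped": 0, "rows_used": 0}
    counts = df.groupby("eye_id")["time_years"].count()
    keep_eyes = set(counts[counts >= min_exams].index)
    dropped = sorted(set(counts.index) - keep_eyes)
    stats["eyes_dropped"] = len(dropped)
    if dropped:
        logger.info("dropped %d eye(s) with fewer than %d scans: %s",
                    len(dropped), min_exams, dropped)
    profiles = []
    df = df.reset_index(drop=True)
    sub = df[df["eye_id"].isin(keep_eyes)]
    sub = sub.sort_values(["eye_id", "time_years"], kind="mergesort")
    _check_monotone_times(sub, "OCT table")
    for i, r in sub.iterrows():
        profiles.append(CpRNFLProfile(
            eye_id=str(r["eye_id"]), subject_id=str(r["subject_id"]),
            laterality=str(r["laterality"]), time_years=float(r["time_years"]),
            thickness_um=tuple(thick[i]),
            fovea_onh_angle_deg=float(r["fovea_onh_angle_deg"])))
    stats["rows_used"] = len(profiles)
    stats["rows_excluded_few_exams"] = stats["rows_in"] - stats["rows_used"]
    return profiles, stats
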