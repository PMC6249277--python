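"""Structure-function maps and sector aggregation.

A :class:`SectorMap` couples two partitions: an assignment of the 52
analyzed 24-2 visual-field points to named field sectors, and a set of
half-open angular arcs partitioning the 360-degree circumpapillary scan into
named optic-disc sectors.  The ``correspondence`` table links each field
sector to the disc sector its retinal nerve fibers enter (same-colored
regions of a structure-function map).

Angular convention
------------------
All arcs are expressed in the canonical TSNIT frame: 0 degrees at the
temporal meridian, increasing through superior, right-eye orientation.
Sample ``k`` of a 768-point profile is centred at ``(k + 0.5) * 360/768``
degrees.  Left-eye data are mirrored into this frame before aggregation.

Built-in maps
-------------
``spectralis6``
    The instrument's six standard disc sectors (T/TS/NS/N/NI/TI); no field
    assignment.
``garway_heath``
    Six field sectors with the classic disc arcs (temporal 311-40, 46-degree
    superotemporal/superonasal wedges, 110-degree nasal); no angle
    adjustment.
``nakanishi``
    A map whose disc-arc boundaries are rotated per-eye by the fovea-to-
    optic-nerve-head-centre angle relative to a reference angle.  The point
    grouping shipped here is a synthetic placeholder with the same structure
    as the published map (the original grouping is not reproduced in open
    form); edit ``data/nakanishi.csv`` to substitute exact boundaries.

Maps are loaded from plain CSV files (columns ``kind`` [vf|disc],
``label``, ``x_deg,y_deg`` for vf rows, ``start_deg,end_deg`` for disc
rows) so boundaries can be corrected without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import CpRNFLProfile, N_PROFILE_SAMPLES, VisualFieldExam
from .errors import ValidationError
from .grids import GRID_24_2
from .transforms import antilog_to_db, db_to_antilog

GLOBAL = "global"

#: Field-sector -> disc-sector links for the built-in maps.  Field labels
#: name the sector's position in the visual field; the linked disc sector is
#: the one reached by the corresponding retinal nerve fibers (field and
#: retina are inverted in both axes).
_BUILTIN_CORRESPONDENCE = {
    "garway_heath": {
        "central": "temporal",
        "temporal": "nasal",
        "nasal_superior": "temporal_inferior",
        "temporal_superior": "nasal_inferior",
        "nasal_inferior": "temporal_superior",
        "temporal_inferior": "nasal_superior",
    },
}
_BUILTIN_CORRESPONDENCE["nakanishi"] = dict(_BUILTIN_CORRESPONDENCE["garway_heath"])

#: Reference fovea-ONH angle (degrees) about which adjusted maps rotate;
#: near the typical population mean.
DEFAULT_REFERENCE_ANGLE_DEG = -7.0


def _arc_contains(start: float, end: float, angle: float) -> bool:
    """Membership of ``angle`` in the half-open arc [start, end), mod 360."""
    start, end, angle = start % 360.0, end % 360.0, angle % 360.0
    if start <= end:
        return start <= angle < end
    return angle >= start or angle < end


def _arc_length(start: float, end: float) -> float:
    return (end - start) % 360.0 or 360.0


@dataclass(frozen=True)
class SectorMap:
    """A structure-function map (field partition + disc arcs + links)."""

    name: str
    vf_assignment: dict  # (x, y) -> field sector label; may be empty
    disc_sectors: tuple  # ((label, start_deg, end_deg), ...)
    requires_fovea_onh_adjustment: bool = False
    correspondence: dict = field(default_factory=dict)
    reference_angle_deg: float = DEFAULT_REFERENCE_ANGLE_DEG

    def __post_init__(self):
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self):
        total = sum(_arc_length(s, e) for _, s, e in self.disc_sectors)
        if not math.isclose(total, 360.0, abs_tol=1e-9):
            raise ValidationError(
                f"map {self.name!r}: disc arcs cover {total} degrees, expected 360")
        # pairwise overlap check at arc midpoints and quarter points
        for i, (la, sa, ea) in enumerate(self.disc_sectors):
            for frac in (0.25, 0.5, 0.75):
                ang = (sa + frac * _arc_length(sa, ea)) % 360.0
                hits = [lb for lb, sb, eb in self.disc_sectors if _arc_contains(sb, eb, ang)]
                if len(hits) != 1:
                    raise ValidationError(
                        f"map {self.name!r}: angle {ang:.2f} lies in arcs {hits}")
        if self.vf_assignment:
            if set(self.vf_assignment) != set(GRID_24_2):
                raise ValidationError(
                    f"map {self.name!r}: field assignment must cover all 52 points")
            disc_labels = {l for l, _, _ in self.disc_sectors}
            for vlab in self.vf_labels:
                dlab = self.correspondence.get(vlab)
                if dlab is None or dlab not in disc_labels:
                    raise ValidationError(
                        f"map {self.name!r}: field sector {vlab!r} has no "
                        f"corresponding disc sector")

    # -- introspection ---------------------------------------------------
    @property
    def disc_labels(self) -> tuple:
        return tuple(l for l, _, _ in self.disc_sectors)

    @property
    def vf_labels(self) -> tuple:
        return tuple(sorted(set(self.vf_assignment.values())))

    def vf_points(self, label: str) -> tuple:
        return tuple(p for p, l in self.vf_assignment.items() if l == label)

    def vf_hemifield(self, label: str) -> str:
        """'superior' / 'inferior' if all of a sector's points lie in one
        hemifield, else 'mixed'."""
        ys = [y for (_, y), l in self.vf_assignment.items() if l == label]
        if all(y > 0 for y in ys):
            return "superior"
        if all(y < 0 for y in ys):
            return "inferior"
        return "mixed"

    def rotated(self, delta_deg: float) -> "SectorMap":
        """Return a copy with every disc-arc boundary shifted by ``delta_deg``."""
        arcs = tuple((l, (s + delta_deg) % 360.0, (e + delta_deg) % 360.0)
                     for l, s, e in self.disc_sectors)
        return replace(self, disc_sectors=arcs)


# ---------------------------------------------------------------------------
# map loading

def load_map(source, name: str, requires_fovea_onh_adjustment: bool = False,
             correspondence: dict | None = None,
             reference_angle_deg: float = DEFAULT_REFERENCE_ANGLE_DEG) -> SectorMap:
    """Load a :class:`SectorMap` from a map-definition CSV."""
    df = pd.read_csv(source)
    need = {"kind", "label"}
    if not need.issubset(df.columns):
        raise ValidationError(f"map file for {name!r} lacks columns {need}")
    vf = {}
    for _, r in df[df["kind"] == "vf"].iterrows():
        vf[(int(r["x_deg"]), int(r["y_deg"]))] = str(r["label"])
    disc = tuple((str(r["label"]), float(r["start_deg"]), float(r["end_deg"]))
                 for _, r in df[df["kind"] == "disc"].iterrows())
    if correspondence is None:
        correspondence = {l: l for l in set(vf.values())}
    return SectorMap(name=name, vf_assignment=vf, disc_sectors=disc,
                     requires_fovea_onh_adjustment=requires_fovea_onh_adjustment,
                     correspondence=correspondence,
                     reference_angle_deg=reference_angle_deg)


def builtin_maps() -> dict:
    """The three built-in maps, freshly loaded from the packaged data files."""
    data = resources.files("glauprog") / "data"
    out = {}
    out["spectralis6"] = load_map(data / "spectralis6.csv", "spectralis6")
    out["garway_heath"] = load_map(
        data / "garway_heath.csv", "garway_heath",
        correspondence=_BUILTIN_CORRESPONDENCE["garway_heath"])
    out["nakanishi"] = load_map(
        data / "nakanishi.csv", "nakanishi",
        requires_fovea_onh_adjustment=True,
        correspondence=_BUILTIN_CORRESPONDENCE["nakanishi"])
    return out


def get_map(name: str) -> SectorMap:
    maps = builtin_maps()
    if name not in maps:
        raise ValidationError(f"unknown map {name!r}; built-ins: {sorted(maps)}")
    return maps[name]


# ---------------------------------------------------------------------------
# laterality

def normalize_laterality(obj):
    """Mirror a left-eye exam or profile into the right-eye frame.

    Right-eye input is returned unchanged.  For exams the field
    x-coordinates are negated; for profiles the sample order is reversed
    about the temporal meridian (sample ``k`` -> ``767 - k``), which is the
    angular reflection ``theta -> -theta``.  The fovea-ONH angle keeps its
    sign (it is defined relative to the horizontal in either eye).  The
    operation is an involution: applying the OS mirror twice restores the
    original data.
    """
    if obj.laterality == "OD":
        return obj
    if obj.laterality != "OS":
        raise ValidationError(f"unknown laterality {obj.laterality!r}")
    if isinstance(obj, VisualFieldExam):
        pts = {(-x, y): v for (x, y), v in obj.points.items()}
        return replace(obj, laterality="OD", points=pts)
    if isinstance(obj, CpRNFLProfile):
        return replace(obj, laterality="OD",
                       thickness_um=tuple(reversed(obj.thickness_um)))
    raise TypeError(f"cannot normalize object of type {type(obj).__name__}")


def denormalize_laterality(obj, target: str):
    """Inverse of :func:`normalize_laterality`: express an OD-frame record
    in the ``target`` eye's own frame."""
    if target == "OD":
        return obj
    if target != "OS":
        raise ValidationError(f"unknown laterality {target!r}")
    if isinstance(obj, VisualFieldExam):
        pts = {(-x, y): v for (x, y), v in obj.points.items()}
        return replace(obj, laterality="OS", points=pts)
    if isinstance(obj, CpRNFLProfile):
        return replace(obj, laterality="OS",
                       thickness_um=tuple(reversed(obj.thickness_um)))
    raise TypeError(f"cannot mirror object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# aggregation

def sample_angles(n: int = N_PROFILE_SAMPLES) -> np.ndarray:
    """Centre angle (degrees) of each profile sample in the canonical frame."""
    return (np.arange(n) + 0.5) * (360.0 / n)


def assign_samples(disc_sectors, n: int = N_PROFILE_SAMPLES) -> np.ndarray:
    """Label index (into ``disc_sectors``) for each of ``n`` samples."""
    angles = sample_angles(n)
    out = np.full(n, -1, dtype=int)
    for i, (_, s, e) in enumerate(disc_sectors):
        s, e = s % 360.0, e % 360.0
        if s <= e:
            mask = (angles >= s) & (angles < e)
        else:
            mask = (angles >= s) | (angles < e)
        out[mask] = i
    if np.any(out < 0):
        raise ValidationError("disc arcs do not cover every profile sample")
    return out


def sectorize_profile(profile: CpRNFLProfile, sector_map: SectorMap,
                      reference_angle_deg: float | None = None) -> dict:
    """Arithmetic sector means of a circumpapillary profile, plus the global
    mean over all 768 samples.

    The profile is mirrored to the right-eye frame first.  For maps flagged
    ``requires_fovea_onh_adjustment`` the arc boundaries are rotated by the
    eye's fovea-ONH angle minus the map's reference angle before samples are
    binned.

    Returns ``{sector_label: mean_um}`` including the ``'global'`` entry.
    """
    prof = normalize_laterality(profile)
    m = sector_map
    if m.requires_fovea_onh_adjustment:
        if not np.isfinite(prof.fovea_onh_angle_deg):
            raise ValidationError(
                f"map {m.name!r} requires the fovea-ONH angle, missing for "
                f"eye {profile.eye_id!r}")
        ref = (m.reference_angle_deg if reference_angle_deg is None
               else reference_angle_deg)
        m = m.rotated(prof.fovea_onh_angle_deg - ref)
    thick = prof.thickness
    idx = assign_samples(m.disc_sectors)
    out = {GLOBAL: float(thick.mean())}
    for i, (label, _, _) in enumerate(m.disc_sectors):
        out[label] = float(thick[idx == i].mean())
    return out


MEAN_MODES = ("geometric_db", "arith_antilog")


def _sector_mean_db(values_db: np.ndarray, mean_mode: str) -> float:
    if mean_mode == "geometric_db":
        # arithmetic mean on the dB scale == geometric mean on 1/L scale
        return float(np.mean(values_db))
    if mean_mode == "arith_antilog":
        return float(antilog_to_db(np.mean(db_to_antilog(values_db))))
    raise ValidationError(f"unknown mean_mode {mean_mode!r}")


def vf_sector_value(exam: VisualFieldExam, sector_map: SectorMap,
                    value_kind: str = "threshold",
                    mean_mode: str = "geometric_db") -> dict:
    """Sector means of a visual-field exam, expressed in dB.

    ``mean_mode='geometric_db'`` averages the dB values arithmetically (the
    conventional summary, equivalently a geometric mean of the linear
    sensitivities).  ``mean_mode='arith_antilog'`` converts each point to
    the 1/Lambert scale, averages arithmetically, and reports the result in
    dB.  Returns ``{sector_label: value_dB}`` including ``'global'``.
    """
    if not sector_map.vf_assignment:
        raise ValidationError(f"map {sector_map.name!r} has no field-point assignment")
    ex = normalize_laterality(exam)
    vals = ex.values(value_kind)
    out = {GLOBAL: _sector_mean_db(np.array(list(vals.values())), mean_mode)}
    for label in sector_map.vf_labels:
        pts = sector_map.vf_points(label)
        missing = [p for p in pts if p not in vals]
        if missing:
            raise ValidationError(f"points {missing} not present in exam")
        out[label] = _sector_mean_db(np.array([vals[p] for p in pts]), mean_mode)
    return out


class SectorAggregator(TransformerMixin, BaseEstimator):
    """Transformer turning per-visit records into a tidy sector-value table.

    Parameters
    ----------
    map_name : str
        One of the built-in map names.
    value_kind : str
        'threshold' or 'total_deviation' (visual-field exams only).
    mean_mode : str
        Field averaging mode; see :func:`vf_sector_value`.

    ``transform`` accepts an iterable of :class:`VisualFieldExam` and/or
    :class:`CpRNFLProfile` records and returns a DataFrame with columns
    ``subject_id, eye_id, time_years, modality, sector, scale, mean_mode,
    value``.
    """

    def __init__(self, map_name: str = "garway_heath",
                 value_kind: str = "threshold",
                 mean_mode: str = "geometric_db"):
        self.map_name = map_name
        self.value_kind = value_kind
        self.mean_mode = mean_mode

    def fit(self, X=None, y=None):
        self.map_ = get_map(self.map_name)
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "map_"):
            self.fit()
        rows = []
        for rec in X:
            if isinstance(rec, VisualFieldExam):
                if not self.map_.vf_assignment:
                    continue
                vals = vf_sector_value(rec, self.map_, self.value_kind, self.mean_mode)
                for sector, v in vals.items():
                    rows.append((rec.subject_id, rec.eye_id, rec.time_years,
                                 "VF", sector, "dB", self.mean_mode, v))
            elif isinstance(rec, CpRNFLProfile):
                vals = sectorize_profile(rec, self.map_)
                for sector, v in vals.items():
                    rows.append((rec.subject_id, rec.eye_id, rec.time_years,
                                 "OCT", sector, "um", "", v))
            else:
                raise TypeError(f"cannot aggregate record of type {type(rec).__name__}")
        return pd.DataFrame(rows, columns=[
            "subject_id", "eye_id", "time_years", "modality", "sector",
            "scale", "mean_mode", "value"])
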