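"""Sector maps: arc partitions, aggregation, laterality, averaging modes."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glauprog.datatypes import CpRNFLProfile, VisualFieldExam
from glauprog.errors import ValidationError
from glauprog.grids import GRID_24_2
from glauprog.sector_maps import (GLOBAL, SectorAggregator, SectorMap,
                                  assign_samples, denormalize_laterality,
                                  normalize_laterality, sample_angles,
                                  sectorize_profile, vf_sector_value)
from glauprog.transforms import db_to_antilog

N = 768
SPECTRALIS_LABELS = {"temporal", "temporal_superior", "nasal_superior",
                     "nasal", "nasal_inferior", "temporal_inferior"}


def make_profile(thickness, laterality="OD", angle=-7.0, eye="e1", t=0.0):
    return CpRNFLProfile(eye_id=eye, subject_id="s1", laterality=laterality,
                         time_years=t, thickness_um=tuple(thickness),
                         fovea_onh_angle_deg=angle)


def make_exam(values, laterality="OD", t=0.0):
    pts = {p: (float(values[i]), float(values[i]) - 30.0)
           for i, p in enumerate(GRID_24_2)}
    if laterality == "OS":
        pts = {(-x, y): v for (x, y), v in pts.items()}
    return VisualFieldExam(eye_id="e1", subject_id="s1", laterality=laterality,
                           time_years=t, points=pts, md_dB=0.0, psd_dB=0.0)


# ---------------------------------------------------------------------------
# built-in map structure

def test_builtin_disc_sectors_cover_circle(maps):
    for name, m in maps.items():
        idx = assign_samples(m.disc_sectors)
        assert set(idx) == set(range(len(m.disc_sectors)))
        total = sum((e - s) % 360 or 360 for _, s, e in m.disc_sectors)
        assert total == pytest.approx(360.0)


def test_spectralis6_labels_match_instrument_sectors(maps):
    assert set(maps["spectralis6"].disc_labels) == SPECTRALIS_LABELS
    assert not maps["spectralis6"].vf_assignment


def test_garway_heath_field_partition(maps):
    m = maps["garway_heath"]
    assert set(m.vf_assignment) == set(GRID_24_2)
    assert len(m.vf_labels) == 6
    # every field sector is linked to a disc sector of the same map
    assert set(m.correspondence) == set(m.vf_labels)
    assert set(m.correspondence.values()) <= set(m.disc_labels)


def test_nakanishi_requires_angle(maps):
    m = maps["nakanishi"]
    assert m.requires_fovea_onh_adjustment
    prof = make_profile(np.full(N, 80.0), angle=float("nan"))
    with pytest.raises(ValidationError):
        sectorize_profile(prof, m)


def test_overlapping_arcs_rejected():
    with pytest.raises(ValidationError):
        SectorMap(name="bad", vf_assignment={}, disc_sectors=(
            ("a", 0, 200), ("b", 100, 360)))


# ---------------------------------------------------------------------------
# profile aggregation

def test_uniform_profile_all_sectors_equal(maps):
    prof = make_profile(np.full(N, 80.0))
    for m in maps.values():
        vals = sectorize_profile(prof, m)
        assert all(v == pytest.approx(80.0) for v in vals.values())


def test_half_circle_profile_global_mean(maps):
    ang = sample_angles()
    thick = np.where((ang < 90) | (ang >= 270), 100.0, 50.0)
    vals = sectorize_profile(make_profile(thick), maps["spectralis6"])
    assert vals[GLOBAL] == pytest.approx(75.0)
    assert vals["temporal"] == pytest.approx(100.0)
    assert vals["nasal"] == pytest.approx(50.0)


def test_arc_rotation_by_one_bin_shifts_assignment_by_one_index(maps):
    """Exhaustive index oracle over all 768 samples."""
    m = maps["spectralis6"]
    step = 360.0 / N
    base = assign_samples(m.disc_sectors)
    rotated = assign_samples(m.rotated(step).disc_sectors)
    assert np.array_equal(rotated, np.roll(base, 1))
    rotated_back = assign_samples(m.rotated(-step).disc_sectors)
    assert np.array_equal(rotated_back, np.roll(base, -1))


def test_sector_weighted_mean_equals_global(maps, rng):
    for _ in range(25):
        thick = rng.uniform(5, 250, N)
        angle = rng.normal(-7.63, 4.04)
        prof = make_profile(thick, angle=angle)
        for m in maps.values():
            vals = sectorize_profile(prof, m)
            mm = m.rotated(angle - m.reference_angle_deg) \
                if m.requires_fovea_onh_adjustment else m
            idx = assign_samples(mm.disc_sectors)
            w = np.bincount(idx, minlength=len(m.disc_sectors))
            sect = np.array([vals[lab] for lab, _, _ in mm.disc_sectors])
            assert np.average(sect, weights=w) == pytest.approx(
                vals[GLOBAL], abs=1e-9)


def test_rotation_equivariance_of_sector_values(maps, rng):
    """Rotating the profile array together with the arcs leaves sector
    values unchanged."""
    m = maps["spectralis6"]
    thick = rng.uniform(20, 150, N)
    k = 37
    vals = sectorize_profile(make_profile(thick), m)
    vals_rot = sectorize_profile(make_profile(np.roll(thick, k)),
                                 m.rotated(k * 360.0 / N))
    for lab in m.disc_labels:
        assert vals_rot[lab] == pytest.approx(vals[lab], abs=1e-9)


def test_nakanishi_rotation_uses_eye_angle(maps, rng):
    m = maps["nakanishi"]
    thick = rng.uniform(20, 150, N)
    ref = m.reference_angle_deg
    step = 360.0 / N
    # an eye at the reference angle is unrotated
    v0 = sectorize_profile(make_profile(thick, angle=ref), m)
    plain = dataclasses.replace(m, requires_fovea_onh_adjustment=False)
    assert v0 == sectorize_profile(make_profile(thick, angle=ref), plain)
    # an angle offset of exactly one bin rotates the boundaries by one bin
    v1 = sectorize_profile(make_profile(thick, angle=ref + step), m)
    v2 = sectorize_profile(make_profile(thick), plain.rotated(step))
    for lab in m.disc_labels:
        assert v1[lab] == pytest.approx(v2[lab], abs=1e-9)


# ---------------------------------------------------------------------------
# visual-field averaging

def test_equal_points_identical_under_both_modes(maps):
    exam = make_exam(np.full(52, 30.0))
    for mode in ("geometric_db", "arith_antilog"):
        vals = vf_sector_value(exam, maps["garway_heath"], "threshold", mode)
        assert all(v == pytest.approx(30.0) for v in vals.values())


def test_mixed_sector_mean_modes(maps):
    """Half 30 dB, half 20 dB: conventional mean 25 dB, antilog mean
    10*log10(550) ~ 27.404 dB."""
    m = maps["garway_heath"]
    vals = np.zeros(52)
    pts = m.vf_points("central")   # 6 points
    for i, p in enumerate(GRID_24_2):
        vals[i] = 30.0 if (p in pts[:3] or p not in pts) else 20.0
    exam = make_exam(vals)
    geo = vf_sector_value(exam, m, "threshold", "geometric_db")["central"]
    ari = vf_sector_value(exam, m, "threshold", "arith_antilog")["central"]
    assert geo == pytest.approx(25.0)
    assert ari == pytest.approx(10 * np.log10((1000 + 100) / 2), abs=1e-9)
    assert ari == pytest.approx(27.404, abs=1e-3)


def test_single_point_sector_returns_the_point(maps):
    gh = maps["garway_heath"]
    assign = dict(gh.vf_assignment)
    assign[(-27, 3)] = "solo"
    corr = dict(gh.correspondence)
    corr["solo"] = "nasal"
    m = SectorMap(name="custom", vf_assignment=assign,
                  disc_sectors=gh.disc_sectors, correspondence=corr)
    vals = np.full(52, 18.0)
    vals[GRID_24_2.index((-27, 3))] = 7.0
    exam = make_exam(vals)
    for mode in ("geometric_db", "arith_antilog"):
        assert vf_sector_value(exam, m, "threshold", mode)["solo"] == \
            pytest.approx(7.0)


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.floats(min_value=-5, max_value=35), min_size=2, max_size=16))
def test_antilog_mean_dominates_db_mean(values):
    """Arithmetic-geometric mean inequality on the apostilb scale."""
    v = np.asarray(values)
    geo = float(np.mean(v))
    ari = 10 * np.log10(np.mean(db_to_antilog(v)))
    assert ari >= geo - 1e-9
    if np.ptp(v) > 1e-6:
        assert ari > geo
    else:
        assert ari == pytest.approx(geo, abs=1e-6)


def test_geometric_db_is_geometric_mean_on_apostilb_scale(rng):
    v = rng.uniform(0, 35, 20)
    geo_db = float(np.mean(v))
    exp_mean_log = 10 * np.log10(np.exp(np.mean(np.log(db_to_antilog(v)))))
    assert geo_db == pytest.approx(exp_mean_log, abs=1e-9)


# ---------------------------------------------------------------------------
# laterality

def test_normalize_laterality_identity_and_involution(maps, rng):
    prof_od = make_profile(rng.uniform(20, 150, N))
    assert normalize_laterality(prof_od) is prof_od
    prof_os = denormalize_laterality(prof_od, "OS")
    assert prof_os.laterality == "OS"
    back = normalize_laterality(prof_os)
    assert np.allclose(back.thickness_um, prof_od.thickness_um)
    exam_od = make_exam(rng.uniform(0, 35, 52))
    exam_os = denormalize_laterality(exam_od, "OS")
    back = normalize_laterality(exam_os)
    assert back.points == exam_od.points


def test_mirrored_wedge_lands_at_reflected_angle(rng):
    """Sample-by-sample oracle: mirroring about the temporal meridian sends
    sample k to 767-k."""
    thick = np.full(N, 80.0)
    lo, hi = 100, 140   # wedge somewhere superior
    thick[lo:hi] = 40.0
    prof_os = denormalize_laterality(make_profile(thick), "OS")
    mirrored = np.asarray(prof_os.thickness_um)
    for k in range(N):
        assert mirrored[k] == thick[N - 1 - k]
    # after normalization the wedge is back where it started
    again = normalize_laterality(prof_os)
    assert np.array_equal(np.asarray(again.thickness_um), thick)


def test_os_exam_sectorizes_like_mirrored_od(maps, rng):
    vals = rng.uniform(0, 35, 52)
    exam_od = make_exam(vals)
    exam_os = denormalize_laterality(exam_od, "OS")
    m = maps["garway_heath"]
    v1 = vf_sector_value(exam_od, m, "threshold", "geometric_db")
    v2 = vf_sector_value(exam_os, m, "threshold", "geometric_db")
    assert v1 == pytest.approx(v2)


def test_unknown_laterality_rejected():
    with pytest.raises(ValidationError):
        make_profile(np.full(N, 80.0), laterality="XX")


# ---------------------------------------------------------------------------
# transformer surface

def test_sector_aggregator_tidy_output(maps, rng):
    records = [make_exam(rng.uniform(0, 35, 52)),
               make_profile(rng.uniform(20, 150, N))]
    agg = SectorAggregator(map_name="garway_heath")
    df = agg.fit().transform(records)
    assert set(df["modality"]) == {"VF", "OCT"}
    assert GLOBAL in set(df["sector"])
    assert {"subject_id", "eye_id", "time_years", "sector", "value"} <= \
        set(df.columns)
    assert len(df[df.modality == "OCT"]) == 7   # 6 sectors + global
    assert len(df[df.modality == "VF"]) == 7
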