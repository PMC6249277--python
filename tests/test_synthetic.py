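"""Synthetic cohort generator: determinism, moments, identifiability, IO."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from glauprog import SynthConfig, generate_cohort, write_cohort
from glauprog.errors import ValidationError
from glauprog.io import read_oct_table, read_vf_table
from glauprog.lmm import ols_oracle
from glauprog.sector_maps import get_map, sectorize_profile, vf_sector_value
from glauprog.synthetic import Cohort
from glauprog.transforms import db_to_antilog


def test_seeded_reproducibility():
    cfg = SynthConfig(n_subjects=5, seed=123)
    assert generate_cohort(cfg) == generate_cohort(cfg)


def test_different_seeds_differ():
    a = generate_cohort(SynthConfig(n_subjects=5, seed=1))
    b = generate_cohort(SynthConfig(n_subjects=5, seed=2))
    assert a != b


def test_expected_eye_count_matches_bilateral_fraction():
    c = generate_cohort(SynthConfig(n_subjects=100, bilateral_fraction=0.31,
                                    seed=0))
    # E = 131 eyes; allow 3 binomial SDs (~14)
    assert abs(len(c.eyes) - 131) <= 14
    per_subject = pd.Series([e.subject_id for e in c.eyes]).value_counts()
    assert per_subject.max() <= 2
    assert len(per_subject) == 100


def test_visit_structure(small_cohort):
    for eye in small_cohort.eyes:
        times = [v.time_years for v in small_cohort.eye_visits(eye.eye_id)]
        assert len(times) >= 4
        assert times[0] == 0.0
        assert all(b > a for a, b in zip(times, times[1:]))


def test_baseline_moment_recovery():
    cfg = SynthConfig(n_subjects=160, seed=3)
    c = generate_cohort(cfg)
    assert len(c.eyes) >= 200
    md = np.array([e.baseline_md_db for e in c.eyes])
    se = cfg.baseline_md_sd / np.sqrt(len(md))
    assert abs(md.mean() - cfg.baseline_md_mean) <= 3 * se
    glob = np.array([e.struct_intercept_um["global"] for e in c.eyes])
    se_g = cfg.baseline_rnflt_sd / np.sqrt(len(glob))
    assert abs(glob.mean() - cfg.baseline_rnflt_mean) <= 3 * se_g


def test_noise_free_per_eye_ols_recovers_slopes(noise_free_cohort,
                                                noise_free_config):
    cfg = noise_free_config
    m = get_map(cfg.link_map)
    eye = noise_free_cohort.eyes[0]
    rows_oct, rows_vf = [], []
    for v in noise_free_cohort.eye_visits(eye.eye_id):
        rows_oct.append((eye.subject_id, eye.eye_id, v.time_years,
                         sectorize_profile(v.profile, m)["global"]))
        rows_vf.append((eye.subject_id, eye.eye_id, v.time_years,
                        vf_sector_value(v.exam, m)["temporal_superior"]))
    cols = ["subject_id", "eye_id", "time_years", "value"]
    o_oct = ols_oracle(pd.DataFrame(rows_oct, columns=cols))
    o_vf = ols_oracle(pd.DataFrame(rows_vf, columns=cols))
    assert float(o_oct["slope"].iloc[0]) == pytest.approx(
        cfg.slope_rnflt_mean, abs=1e-9)
    assert float(o_vf["slope"].iloc[0]) == pytest.approx(
        cfg.slope_md_mean, abs=1e-9)


def test_sector_ols_matches_per_sector_truth():
    """With observation noise off, each sector's fitted line equals the
    latent per-sector slope even under focal heterogeneity."""
    cfg = SynthConfig(n_subjects=4, vf_point_noise_sd=0.0,
                      oct_sector_noise_sd=0.0, seed=11)
    c = generate_cohort(cfg)
    m = get_map(cfg.link_map)
    eye = c.eyes[1]
    for sector in ("temporal_inferior", "nasal"):
        rows = [(eye.subject_id, eye.eye_id, v.time_years,
                 sectorize_profile(v.profile, m)[sector])
                for v in c.eye_visits(eye.eye_id)]
        o = ols_oracle(pd.DataFrame(
            rows, columns=["subject_id", "eye_id", "time_years", "value"]))
        assert float(o["slope"].iloc[0]) == pytest.approx(
            eye.struct_slope_um_per_year[sector], abs=1e-9)


def test_link_consistency(noise_free_cohort, noise_free_config):
    """With zero point noise, converting a sector's dB mean to the linear
    scale recovers a * max(F - b, 0) for the eye's latent functional
    thickness F."""
    cfg = noise_free_config
    m = get_map(cfg.link_map)
    eye = noise_free_cohort.eyes[0]
    v0 = noise_free_cohort.eye_visits(eye.eye_id)[0]
    vals = vf_sector_value(v0.exam, m, "threshold", "geometric_db")
    for sector in m.vf_labels:
        F = eye.func_thickness_um[sector]
        expected = cfg.link_gain_a * max(F - cfg.link_floor_b, 0.0)
        assert db_to_antilog(vals[sector]) == pytest.approx(
            expected, abs=1e-9 * max(1.0, expected))


@pytest.mark.parametrize("kwargs", [
    dict(n_subjects=0),
    dict(bilateral_fraction=1.5),
    dict(baseline_md_sd=-1.0),
    dict(sf_slope_correlation=1.2),
    dict(link_gain_a=0.0),
    dict(visit_interval_mean=0.0),
    dict(followup_years_mean=float("nan")),
])
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValidationError):
        SynthConfig(**kwargs)


def test_write_cohort_files_and_round_trip(tmp_path):
    cfg = SynthConfig(n_subjects=2, bilateral_fraction=1.0, seed=5)
    c = generate_cohort(cfg)
    manifest = write_cohort(c, tmp_path)
    assert manifest["vf"]["rows"] == len(c.visits)
    assert manifest["oct"]["rows"] == len(c.visits)
    assert manifest["eyes"]["rows"] == len(c.eyes) == 4
    assert (tmp_path / "synth_config.yaml").exists()

    exams, _ = read_vf_table(tmp_path / "vf.csv")
    profiles, _ = read_oct_table(tmp_path / "oct.csv")
    assert len(exams) == len(profiles) == len(c.visits)
    orig = {(v.eye_id, v.time_years): v for v in c.visits}
    for ex in exams:
        v = orig[(ex.eye_id, ex.time_years)]
        assert ex.laterality == v.exam.laterality
        for p, (thr, td) in ex.points.items():
            assert thr == pytest.approx(v.exam.points[p][0], abs=1e-9)
            assert td == pytest.approx(v.exam.points[p][1], abs=1e-9)
    for pr in profiles:
        v = orig[(pr.eye_id, pr.time_years)]
        assert np.allclose(pr.thickness_um, v.profile.thickness_um, atol=1e-9)
        assert pr.laterality == v.profile.laterality


def test_write_empty_cohort_headers_only(tmp_path):
    empty = Cohort(config=SynthConfig(n_subjects=1, seed=0), subjects=(),
                   eyes=(), visits=())
    write_cohort(empty, tmp_path)
    vf = pd.read_csv(tmp_path / "vf.csv")
    assert len(vf) == 0 and "md_dB" in vf.columns
    oct_df = pd.read_csv(tmp_path / "oct.csv")
    assert len(oct_df) == 0 and "t_000" in oct_df.columns


def test_slope_correlation_structure():
    """Per-eye structural and functional slopes carry the configured latent
    correlation (up to sampling error at ~260 eyes)."""
    cfg = SynthConfig(n_subjects=200, sf_slope_correlation=0.6,
                      slope_rnflt_sector_sd=0.0, slope_md_sector_sd=0.0,
                      seed=17)
    c = generate_cohort(cfg)
    s = np.array([e.struct_slope_um_per_year["global"] for e in c.eyes])
    f = np.array([e.func_slope_db_per_year["global"] for e in c.eyes])
    r = np.corrcoef(s, f)[0, 1]
    assert r == pytest.approx(0.6, abs=0.12)
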