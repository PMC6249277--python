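"""End-to-end runner: simulate/load -> sectorize -> transform -> fit -> correlate -> report.

The pipeline chains the package's stages over a configurable variant grid:
two structure-function maps, threshold or total-deviation field values, two
field averaging modes, linear or antilog field scales, and linear or
logarithmic thickness scales.  Each (map, modality, sector, variant) series
gets its own nested random-slope mixed-model fit; per-eye BLUPs are then
correlated across modalities and corresponding-sector comparisons and
rankings are written as tidy CSV tables plus a machine-readable run log.

All randomness flows from the configured seed, so a rerun with the same
configuration and inputs reproduces every output byte-for-byte (except the
timestamp field of the run log).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import PipelineStageError, ValidationError
from .io import read_oct_table, read_vf_table
from .lmm import fit_lmm
from .sector_maps import GLOBAL, get_map, sectorize_profile, vf_sector_value
from .structure_function import (best_pairs, compare_corresponding,
                                 compare_variants, correlate_blups)
from .synthetic import SynthConfig, generate_cohort, write_cohort
from .transforms import convert_scale

logger = logging.getLogger(__name__)

VF_SCALES = ("dB", "one_over_L")
OCT_SCALES = ("um", "LogRNFLT")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source must be set: either ``synth`` (a
    :class:`SynthConfig` describing a cohort to simulate) or both
    ``vf_path`` and ``oct_path`` (CSV tables per the io schemas).
    """

    synth: SynthConfig | None = None
    vf_path: str | None = None
    oct_path: str | None = None
    out_dir: str = "glauprog_out"
    maps: tuple = ("garway_heath", "nakanishi")
    value_kinds: tuple = ("threshold", "total_deviation")
    mean_modes: tuple = ("geometric_db", "arith_antilog")
    vf_scales: tuple = VF_SCALES
    oct_scales: tuple = OCT_SCALES
    which: tuple = ("baseline", "slope")
    lmm_method: str = "reml"
    re_structure: str = "unstructured"
    scheme: str = "paired_by_vf_sector"
    fp_max: float = 1.0 / 3.0
    drop_first_lifetime: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        has_synth = self.synth is not None
        has_paths = self.vf_path is not None and self.oct_path is not None
        if has_synth == has_paths:
            raise ValidationError(
                "exactly one of (synth config) or (vf_path and oct_path) "
                "must be provided")
        if has_paths:
            out = Path(self.out_dir).resolve()
            for p in (self.vf_path, self.oct_path):
                if Path(p).resolve().parent == out:
                    raise ValidationError(
                        "output directory must be distinct from input location")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        synth = raw.pop("synth", None)
        if synth is not None:
            synth = SynthConfig(**synth)
        for key in ("maps", "value_kinds", "mean_modes", "vf_scales",
                    "oct_scales", "which"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(synth=synth, **raw)


def _stage(name):
    """Decorator-free stage wrapper: re-raise any error with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, str(exc)) from exc
            return False
    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the result manifest."""
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    manifest = {"seed": config.seed, "versions": _versions(), "stages": {}}

    # -- simulate / load -------------------------------------------------
    with _stage("simulate"):
        if config.synth is not None:
            cfg = dataclasses.replace(config.synth, seed=config.seed)
            cohort = generate_cohort(cfg)
            cohort_dir = out / "cohort"
            write_cohort(cohort, cohort_dir)
            vf_path = cohort_dir / "vf.csv"
            oct_path = cohort_dir / "oct.csv"
            manifest["stages"]["simulate"] = {
                "n_subjects": len(cohort.subjects), "n_eyes": len(cohort.eyes),
                "n_visits": len(cohort.visits)}
        else:
            vf_path, oct_path = config.vf_path, config.oct_path

    with _stage("sectorize"):
        for p, what in ((vf_path, "visual-field"), (oct_path, "OCT")):
            if not Path(p).exists():
                raise PipelineStageError("sectorize", f"missing {what} table: {p}")
        exams, vf_stats = read_vf_table(vf_path, fp_max=config.fp_max,
                                        drop_first_lifetime=config.drop_first_lifetime)
        profiles, oct_stats = read_oct_table(oct_path)
        assert vf_stats["rows_in"] == (vf_stats["rows_used"]
                                       + vf_stats["rows_excluded_unreliable"]
                                       + vf_stats["rows_excluded_first_lifetime"]
                                       + vf_stats["rows_excluded_few_exams"])
        assert oct_stats["rows_in"] == (oct_stats["rows_used"]
                                        + oct_stats["rows_excluded_few_exams"])
        manifest["stages"]["load"] = {"vf": vf_stats, "oct": oct_stats}
        maps = {name: get_map(name) for name in config.maps}

        vf_rows, oct_rows = [], []
        for name, m in maps.items():
            for ex in exams:
                for vk in config.value_kinds:
                    for mm in config.mean_modes:
                        vals = vf_sector_value(ex, m, vk, mm)
                        for sector, v in vals.items():
                            vf_rows.append((name, vk, mm, ex.subject_id,
                                            ex.eye_id, ex.time_years, sector, v))
            for pr in profiles:
                vals = sectorize_profile(pr, m)
                for sector, v in vals.items():
                    oct_rows.append((name, pr.subject_id, pr.eye_id,
                                     pr.time_years, sector, v))
        vf_sectors = pd.DataFrame(vf_rows, columns=[
            "map", "value_kind", "mean_mode", "subject_id", "eye_id",
            "time_years", "sector", "value_db"])
        oct_sectors = pd.DataFrame(oct_rows, columns=[
            "map", "subject_id", "eye_id", "time_years", "sector", "value_um"])
        md_rows = [(ex.subject_id, ex.eye_id, ex.time_years, ex.md_dB)
                   for ex in exams]
        md_series = pd.DataFrame(md_rows, columns=["subject_id", "eye_id",
                                                   "time_years", "value"])

    # -- transform + fit --------------------------------------------------
    with _stage("fit"):
        fits = {}
        fit_rows, blup_rows = [], []

        def do_fit(series, label):
            lf = fit_lmm(series, method=config.lmm_method,
                         re_structure=config.re_structure, label=label)
            key = tuple(sorted(label.items()))
            fits[key] = lf
            fit_rows.append({**label,
                             "beta0": lf.beta0, "beta0_se": lf.se[0],
                             "beta0_lo": lf.ci[0, 0], "beta0_hi": lf.ci[0, 1],
                             "beta1": lf.beta1, "beta1_se": lf.se[1],
                             "beta1_lo": lf.ci[1, 0], "beta1_hi": lf.ci[1, 1],
                             "sigma2": lf.sigma2,
                             "converged": lf.converged,
                             "degenerate": lf.degenerate,
                             "re_structure": lf.re_structure_used,
                             "n_eyes": lf.n_eyes, "n_obs": lf.n_obs})
            for eye, r in lf.blups.iterrows():
                blup_rows.append({**label, "eye_id": eye,
                                  "subject_id": r["subject_id"],
                                  "baseline": r["baseline"],
                                  "slope": r["slope"]})
            return lf

        # summary series: perimetric mean deviation, global thickness
        do_fit(md_series, {"map": "summary", "modality": "VF", "sector": "MD",
                           "value_kind": "md", "mean_mode": "", "scale": "dB"})
        for name in config.maps:
            sub = oct_sectors[(oct_sectors["map"] == name)
                              & (oct_sectors["sector"] == GLOBAL)]
            series = sub.rename(columns={"value_um": "value"})[
                ["subject_id", "eye_id", "time_years", "value"]]
            do_fit(series, {"map": name, "modality": "OCT", "sector": GLOBAL,
                            "value_kind": "", "mean_mode": "", "scale": "um"})
            break  # the global profile mean is map-independent

        for name, m in maps.items():
            for sector in m.vf_labels:
                for vk in config.value_kinds:
                    for mm in config.mean_modes:
                        base = vf_sectors[(vf_sectors["map"] == name)
                                          & (vf_sectors["sector"] == sector)
                                          & (vf_sectors["value_kind"] == vk)
                                          & (vf_sectors["mean_mode"] == mm)]
                        for scale in config.vf_scales:
                            series = base.rename(columns={"value_db": "value"})[
                                ["subject_id", "eye_id", "time_years", "value"]].copy()
                            series["value"] = convert_scale(series["value"],
                                                            "dB", scale)
                            do_fit(series, {"map": name, "modality": "VF",
                                            "sector": sector, "value_kind": vk,
                                            "mean_mode": mm, "scale": scale})
            for sector in m.disc_labels:
                base = oct_sectors[(oct_sectors["map"] == name)
                                   & (oct_sectors["sector"] == sector)]
                for scale in config.oct_scales:
                    series = base.rename(columns={"value_um": "value"})[
                        ["subject_id", "eye_id", "time_years", "value"]].copy()
                    series["value"] = convert_scale(series["value"], "um", scale)
                    do_fit(series, {"map": name, "modality": "OCT",
                                    "sector": sector, "value_kind": "",
                                    "mean_mode": "", "scale": scale})
        manifest["stages"]["fit"] = {"n_fits": len(fit_rows)}

    # -- correlate ---------------------------------------------------------
    with _stage("correlate"):
        def blup_table(label_filter, sectors, quantity):
            cols = {}
            for key, lf in fits.items():
                lab = dict(key)
                if all(lab.get(k) == v for k, v in label_filter.items()) \
                        and lab["sector"] in sectors:
                    cols[lab["sector"]] = lf.blups[quantity]
            if not cols:
                return None
            return pd.DataFrame(cols).reindex(columns=list(sectors))

        results, comp_rows, hemis = [], [], {}
        for name, m in maps.items():
            for s in m.vf_labels:
                hemis[(name, s)] = m.vf_hemifield(s)
            for vk in config.value_kinds:
                for mm in config.mean_modes:
                    for vf_scale in config.vf_scales:
                        for oct_scale in config.oct_scales:
                            for which in config.which:
                                vf_tab = blup_table(
                                    {"map": name, "modality": "VF",
                                     "value_kind": vk, "mean_mode": mm,
                                     "scale": vf_scale}, m.vf_labels, which)
                                oct_tab = blup_table(
                                    {"map": name, "modality": "OCT",
                                     "scale": oct_scale}, m.disc_labels, which)
                                if vf_tab is None or oct_tab is None:
                                    continue
                                res = correlate_blups(
                                    vf_tab, oct_tab, which=which, map_name=name,
                                    correspondence=m.correspondence,
                                    variant={"value_kind": vk, "mean_mode": mm,
                                             "vf_scale": vf_scale,
                                             "oct_scale": oct_scale})
                                results.append(res)
                                try:
                                    comp = compare_corresponding(
                                        res, scheme=config.scheme)
                                    comp_rows.append({
                                        "map": name, "which": which,
                                        "value_kind": vk, "mean_mode": mm,
                                        "vf_scale": vf_scale,
                                        "oct_scale": oct_scale,
                                        "comparison": "corresponding_vs_non",
                                        "test": comp.test, "scheme": comp.scheme,
                                        "statistic": comp.statistic,
                                        "p_value": comp.p_value, "n": comp.n})
                                except ValidationError as exc:
                                    logger.warning("comparison skipped: %s", exc)

        def find(name, vk, mm, vf_scale, oct_scale, which):
            for res in results:
                v = res.variant
                if (res.map_name == name and res.which == which
                        and v.get("value_kind") == vk and v.get("mean_mode") == mm
                        and v.get("vf_scale") == vf_scale
                        and v.get("oct_scale") == oct_scale):
                    return res
            return None

        pairings = [
            ("vf_nonlinear_vs_linear",
             lambda n, vk, mm, w: (find(n, vk, mm, "one_over_L", "um", w),
                                   find(n, vk, mm, "dB", "um", w))),
            ("oct_log_vs_linear",
             lambda n, vk, mm, w: (find(n, vk, mm, "dB", "LogRNFLT", w),
                                   find(n, vk, mm, "dB", "um", w))),
            ("arith_vs_geometric",
             lambda n, vk, mm, w: (find(n, vk, "arith_antilog", "dB", "um", w),
                                   find(n, vk, "geometric_db", "dB", "um", w))),
        ]
        for name in maps:
            for vk in config.value_kinds:
                for which in config.which:
                    for comp_name, picker in pairings:
                        a, b = picker(name, vk, "geometric_db", which)
                        if a is None or b is None or a is b:
                            continue
                        comp = compare_variants(a, b)
                        comp_rows.append({
                            "map": name, "which": which, "value_kind": vk,
                            "mean_mode": "", "vf_scale": "", "oct_scale": "",
                            "comparison": comp_name, "test": comp.test,
                            "scheme": "matched_cells",
                            "statistic": comp.statistic,
                            "p_value": comp.p_value, "n": comp.n})

        ranking = best_pairs(results, hemis) if results else pd.DataFrame()

        # headline summary: MD vs global thickness BLUP correlations
        md_key = tuple(sorted({"map": "summary", "modality": "VF",
                               "sector": "MD", "value_kind": "md",
                               "mean_mode": "", "scale": "dB"}.items()))
        glob_key = None
        for key in fits:
            lab = dict(key)
            if lab["modality"] == "OCT" and lab["sector"] == GLOBAL \
                    and lab["scale"] == "um":
                glob_key = key
                break
        summary = {}
        if md_key in fits and glob_key is not None:
            md_blups = fits[md_key].blups
            g_blups = fits[glob_key].blups
            common = md_blups.index.intersection(g_blups.index)
            for which in ("baseline", "slope"):
                summary[f"md_vs_global_r_{which}"] = float(np.corrcoef(
                    md_blups.loc[common, which], g_blups.loc[common, which])[0, 1])
            summary["md_beta0"] = fits[md_key].beta0
            summary["md_beta1"] = fits[md_key].beta1
            summary["global_rnflt_beta0"] = fits[glob_key].beta0
            summary["global_rnflt_beta1"] = fits[glob_key].beta1
        manifest["summary"] = summary

    # -- report ------------------------------------------------------------
    with _stage("report"):
        paths = {}
        vf_sectors.to_csv(out / "sectors_vf.csv", index=False)
        oct_sectors.to_csv(out / "sectors_oct.csv", index=False)
        pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)
        pd.DataFrame(blup_rows).to_csv(out / "blups.csv", index=False)
        if results:
            pd.concat([r.cells() for r in results], ignore_index=True) \
                .to_csv(out / "correlations.csv", index=False)
            paths["correlations"] = str(out / "correlations.csv")
        pd.DataFrame(comp_rows).to_csv(out / "comparisons.csv", index=False)
        if len(ranking):
            ranking.to_csv(out / "ranking.csv", index=False)
            paths["ranking"] = str(out / "ranking.csv")
        paths.update({"sectors_vf": str(out / "sectors_vf.csv"),
                      "sectors_oct": str(out / "sectors_oct.csv"),
                      "fits": str(out / "fits.csv"),
                      "blups": str(out / "blups.csv"),
                      "comparisons": str(out / "comparisons.csv")})
        manifest["outputs"] = paths
        manifest["elapsed_seconds"] = round(time.time() - t_start, 3)
        run_log = dict(manifest)
        run_log["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(out / "run_log.json", "w") as f:
            json.dump(run_log, f, indent=2, default=str)
    return manifest


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels
    return {"glauprog": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
            "sklearn": sklearn.__version__}
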