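"""Cross-modality correlation of per-eye BLUPs and sector-correspondence tests.

Given per-eye BLUP tables for visual-field sectors and disc sectors (one
model variant each), this module computes the Pearson correlation matrix
over (field sector x disc sector) cells, labels each cell's strength,
flags the map's corresponding cells, and compares corresponding against
non-corresponding correlations with an exact Wilcoxon signed-rank test.

The signed-rank null distribution is computed exactly (all 2^n sign
assignments, via a dynamic program over doubled midranks, so ties are
handled exactly) for n <= 25 pairs, and by a tie-corrected normal
approximation beyond that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: |r| bands for the conventional weak / moderate / strong labels.
STRENGTH_THRESHOLDS = (0.4, 0.7)


def strength_category(r: float, thresholds=STRENGTH_THRESHOLDS) -> str:
    """Label a correlation: |r| < 0.4 weak, < 0.7 moderate, else strong."""
    if not np.isfinite(r):
        return "undefined"
    a = abs(float(r))
    if a > 1:
        raise ValidationError(f"|r|={a} exceeds 1")
    lo, hi = thresholds
    if a < lo:
        return "weak"
    if a < hi:
        return "moderate"
    return "strong"


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank

@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    n: int
    alternative: str
    scheme: str = ""
    detail: dict = field(default_factory=dict)


def _signed_rank_exact(ranks2: np.ndarray, w2_obs: float, alternative: str) -> float:
    """Exact p-value of the signed-rank statistic.

    ``ranks2`` are doubled midranks (integers); ``w2_obs`` the doubled
    observed positive-rank sum.  Enumerates the 2^n equiprobable sign
    assignments through a subset-sum dynamic program.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w = int(round(w2_obs))
    p_ge = float(counts[w:].sum())
    p_le = float(counts[:w + 1].sum())
    if alternative == "greater":
        return min(1.0, p_ge)
    if alternative == "less":
        return min(1.0, p_le)
    return min(1.0, 2.0 * min(p_ge, p_le))


def signed_rank_test(diffs, alternative: str = "two-sided",
                     exact_max_n: int = 25) -> ComparisonResult:
    """Wilcoxon signed-rank test on paired differences.

    Zeros are dropped (Wilcoxon convention); if every difference is zero
    the test carries no evidence and p = 1.  For n <= ``exact_max_n`` the
    exact null distribution is used, handling tied |differences| through
    midranks; otherwise a tie-corrected normal approximation.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValidationError(f"unknown alternative {alternative!r}")
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1:
        raise ValidationError("differences must be one-dimensional")
    d = d[np.isfinite(d)]
    d_nz = d[d != 0]
    n = len(d_nz)
    if n == 0:
        return ComparisonResult(test="wilcoxon_signed_rank", statistic=0.0,
                                p_value=1.0, n=0, alternative=alternative)
    ranks = sps.rankdata(np.abs(d_nz))
    w_plus = float(ranks[d_nz > 0].sum())
    if n <= exact_max_n:
        ranks2 = np.round(2 * ranks).astype(int)
        p = _signed_rank_exact(ranks2, 2 * w_plus, alternative)
        mode = "exact"
    else:
        mu = n * (n + 1) / 4.0
        tie_term = 0.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(((tie_counts ** 3 - tie_counts) / 48.0).sum())
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w_plus - mu) / sigma
        if alternative == "greater":
            p = float(sps.norm.sf(z))
        elif alternative == "less":
            p = float(sps.norm.cdf(z))
        else:
            p = float(2 * sps.norm.sf(abs(z)))
        mode = "normal"
    return ComparisonResult(test="wilcoxon_signed_rank", statistic=w_plus,
                            p_value=p, n=n, alternative=alternative,
                            detail={"mode": mode, "n_zero": int(len(d) - n)})


# ---------------------------------------------------------------------------
# correlation matrices

@dataclass(frozen=True)
class CorrelationResult:
    """Pearson-r matrix over (field sector x disc sector) for one variant."""

    map_name: str
    which: str                 # 'baseline' or 'slope'
    variant: dict              # e.g. {'value_kind': ..., 'mean_mode': ..., 'vf_scale': ..., 'oct_scale': ...}
    r: pd.DataFrame            # field sectors x disc sectors
    n: pd.DataFrame
    corresponding: pd.DataFrame
    n_eyes: int

    @property
    def category(self) -> pd.DataFrame:
        return self.r.map(strength_category)

    def cells(self) -> pd.DataFrame:
        """Tidy per-cell view (vf_sector, oct_sector, r, n, corresponding,
        category)."""
        rows = []
        for vf in self.r.index:
            for oc in self.r.columns:
                rows.append((self.map_name, self.which, vf, oc,
                             self.r.loc[vf, oc], self.n.loc[vf, oc],
                             bool(self.corresponding.loc[vf, oc]),
                             strength_category(self.r.loc[vf, oc])))
        df = pd.DataFrame(rows, columns=["map", "which", "vf_sector",
                                         "oct_sector", "r", "n",
                                         "corresponding", "category"])
        for k, v in self.variant.items():
            df[k] = v
        return df


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN (not 0) when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValidationError("need >= 3 paired observations for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def correlate_blups(vf_blups: pd.DataFrame, oct_blups: pd.DataFrame,
                    which: str = "slope", map_name: str = "",
                    correspondence: dict | None = None,
                    variant: dict | None = None) -> CorrelationResult:
    """Correlate per-eye BLUPs across modalities, sector by sector.

    ``vf_blups`` and ``oct_blups`` are wide tables indexed by ``eye_id``
    with one column per sector, holding the BLUP of the requested quantity
    (``which``).  Only eyes present in both tables enter each cell; cells
    with a zero-variance vector are flagged undefined (NaN), never 0.
    """
    common = vf_blups.index.intersection(oct_blups.index)
    if len(common) < 3:
        raise ValidationError(
            f"only {len(common)} eyes shared between the BLUP tables; need >= 3")
    vf = vf_blups.loc[common]
    oc = oct_blups.loc[common]
    r = pd.DataFrame(index=vf.columns, columns=oc.columns, dtype=float)
    n = pd.DataFrame(index=vf.columns, columns=oc.columns, dtype=int)
    for vs in vf.columns:
        for os_ in oc.columns:
            pair = pd.concat([vf[vs], oc[os_]], axis=1).dropna()
            n.loc[vs, os_] = len(pair)
            r.loc[vs, os_] = (pearson_r(pair.iloc[:, 0], pair.iloc[:, 1])
                              if len(pair) >= 3 else float("nan"))
    corr_map = correspondence or {}
    corresponding = pd.DataFrame(
        [[corr_map.get(vs) == os_ for os_ in oc.columns] for vs in vf.columns],
        index=vf.columns, columns=oc.columns)
    return CorrelationResult(map_name=map_name, which=which,
                             variant=dict(variant or {}), r=r, n=n,
                             corresponding=corresponding, n_eyes=len(common))


def compare_corresponding(result: CorrelationResult,
                          scheme: str = "paired_by_vf_sector",
                          alternative: str = "greater") -> ComparisonResult:
    """Are corresponding-sector correlations higher than non-corresponding?

    ``paired_by_vf_sector`` (default): for each field sector, pair the
    corresponding cell's r against the mean r of that sector's
    non-corresponding cells; exact Wilcoxon signed-rank on the paired
    differences.  ``pooled_rank_sum``: two-sample rank-sum test of all
    corresponding against all non-corresponding cells.  Undefined (NaN)
    cells are excluded with a logged count.
    """
    r = result.r
    mask = result.corresponding
    n_undef = int(r.isna().to_numpy().sum())
    if n_undef:
        logger.info("excluding %d undefined correlation cell(s)", n_undef)
    if scheme == "paired_by_vf_sector":
        diffs = []
        for vf in r.index:
            row = r.loc[vf]
            cm = mask.loc[vf]
            corr_vals = row[cm].dropna()
            non_vals = row[~cm].dropna()
            if len(corr_vals) == 0 or len(non_vals) == 0:
                continue
            diffs.append(float(corr_vals.mean() - non_vals.mean()))
        if len(diffs) < 5:
            raise ValidationError(
                f"only {len(diffs)} usable sector pairs; need >= 5")
        out = signed_rank_test(np.array(diffs), alternative=alternative)
        return ComparisonResult(test=out.test, statistic=out.statistic,
                                p_value=out.p_value, n=out.n,
                                alternative=alternative, scheme=scheme,
                                detail={**out.detail, "differences": diffs})
    if scheme == "pooled_rank_sum":
        m = mask.to_numpy()
        vals = r.to_numpy()
        corr_vals = vals[m]
        non_vals = vals[~m]
        corr_vals = corr_vals[np.isfinite(corr_vals)]
        non_vals = non_vals[np.isfinite(non_vals)]
        alt = {"greater": "greater", "less": "less",
               "two-sided": "two-sided"}[alternative]
        stat, p = sps.mannwhitneyu(corr_vals, non_vals, alternative=alt)
        return ComparisonResult(test="mann_whitney_u", statistic=float(stat),
                                p_value=float(p),
                                n=len(corr_vals) + len(non_vals),
                                alternative=alternative, scheme=scheme)
    raise ValidationError(f"unknown scheme {scheme!r}")


def compare_variants(result_a: CorrelationResult, result_b: CorrelationResult,
                     alternative: str = "two-sided") -> ComparisonResult:
    """Signed-rank test of matched correlation cells between two variants
    (e.g. nonlinear vs linear scales, or the two averaging modes)."""
    if (list(result_a.r.index) != list(result_b.r.index)
            or list(result_a.r.columns) != list(result_b.r.columns)):
        raise ValidationError("variant matrices have different sector layouts")
    d = (result_a.r - result_b.r).to_numpy().ravel()
    return signed_rank_test(d[np.isfinite(d)], alternative=alternative)


def best_pairs(results, hemifield_of: dict | None = None) -> pd.DataFrame:
    """Rank correlation cells, reporting the top cell per map and hemifield.

    ``results`` is an iterable of :class:`CorrelationResult`.
    ``hemifield_of`` maps (map_name, vf_sector) -> 'superior' | 'inferior'
    | 'mixed'; cells from mixed/unknown sectors are ranked under 'mixed'.
    Returns the full ranking (descending r) with a ``rank_in_group`` column;
    the best cell of each (map, hemifield) group has rank 1.
    """
    results = list(results)
    if not results:
        raise ValidationError("need at least one correlation result")
    frames = [res.cells() for res in results]
    df = pd.concat(frames, ignore_index=True)
    hemis = hemifield_of or {}
    df["hemifield"] = [hemis.get((m, s), "mixed")
                       for m, s in zip(df["map"], df["vf_sector"])]
    df = df[np.isfinite(df["r"])]
    df = df.sort_values("r", ascending=False, kind="mergesort").reset_index(drop=True)
    df["rank_in_group"] = df.groupby(["map", "hemifield"])["r"] \
                            .rank(ascending=False, method="first").astype(int)
    return df
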