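"""Two-level random-slope linear mixed models with per-eye BLUPs.

The model for an outcome series Y (one sector/scale/averaging variant) is

    Y_ijt = b0 + b1*t + z0j + z1j*t + z0i|j + z1i|j*t + e_ijt

with random intercepts and slopes at the subject level (j) and, nested
within subject, at the eye level (i|j).  This accommodates two eyes of one
patient without pretending they are independent, tolerates irregular visit
times and unequal visit counts, and yields best linear unbiased predictors
(BLUPs) of each eye's baseline (b0 + z0j + z0i|j) and rate of change
(b1 + z1j + z1i|j).

Estimation is restricted maximum likelihood (REML) by default, through
statsmodels' ``MixedLM``: the subject-level 2x2 covariance is unstructured
(optionally diagonal), the eye-level intercept and slope variances enter as
independent variance components (statsmodels does not support an
eye-level covariance term, so the eye level is always diagonal).  When the
subject-level unstructured fit fails to converge the model is refitted with
a diagonal constraint and the fallback is logged.

Degenerate (noise-free) input - every eye's trajectory an exact line - has
no interior REML optimum; it is detected from the pooled per-eye ordinary
least squares residual and handled by the exact limiting solution: BLUPs
equal the per-eye OLS lines, the residual variance is zero, fixed effects
are the mean of subject-mean OLS coefficients and the level covariances
are the corresponding empirical moments.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.regression.mixed_linear_model import MixedLMParams

from .errors import NotConvergedError, ValidationError

logger = logging.getLogger(__name__)

REQUIRED_COLS = ("subject_id", "eye_id", "time_years", "value")

#: Relative residual-variance threshold below which input is treated as
#: noise-free and the exact limiting solution is returned.
DEGENERATE_RTOL = 1e-10


def _validate_series(df: pd.DataFrame, min_obs_per_eye: int = 2) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"series lacks columns {missing}")
    if df["value"].isna().any() or not np.all(np.isfinite(df["value"])):
        raise ValidationError("series contains non-finite values")
    if (df["time_years"] < 0).any():
        raise ValidationError("times must be >= 0")
    eye_subj = df.groupby("eye_id")["subject_id"].nunique()
    if (eye_subj > 1).any():
        bad = list(eye_subj[eye_subj > 1].index)
        raise ValidationError(f"eyes mapped to multiple subjects: {bad}")
    counts = df.groupby("eye_id")["time_years"].count()
    if (counts < min_obs_per_eye).any():
        bad = list(counts[counts < min_obs_per_eye].index)
        raise ValidationError(
            f"eyes with fewer than {min_obs_per_eye} observations: {bad}")
    return df.sort_values(["subject_id", "eye_id", "time_years"],
                          kind="mergesort").reset_index(drop=True)


def ols_oracle(series: pd.DataFrame) -> pd.DataFrame:
    """Independent per-eye least-squares lines (the BLUP limiting reference).

    Returns a DataFrame indexed by ``eye_id`` with columns ``intercept``,
    ``slope`` and ``rss``.  Raises for eyes whose time vector is degenerate
    (fewer than two distinct times).
    """
    df = _validate_series(pd.DataFrame(series))
    rows = {}
    for eye, g in df.groupby("eye_id", sort=True):
        t = g["time_years"].to_numpy(dtype=float)
        y = g["value"].to_numpy(dtype=float)
        if len(np.unique(t)) < 2:
            raise ValidationError(
                f"eye {eye!r}: need >= 2 distinct times for a least-squares line")
        slope, intercept = np.polyfit(t, y, 1)
        resid = y - (intercept + slope * t)
        rows[eye] = (intercept, slope, float(resid @ resid))
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["intercept", "slope", "rss"])
    out.index.name = "eye_id"
    return out


class RandomSlopeLMM(BaseEstimator):
    """Nested random-slope mixed model estimator (sklearn-style).

    Parameters
    ----------
    method : {'reml', 'ml'}
        Estimation criterion; REML is standard for variance components.
    re_structure : {'unstructured', 'diagonal'}
        Subject-level 2x2 random-effect covariance structure.  The eye
        level is diagonal in either case.  Non-convergence under
        'unstructured' triggers a logged fallback to 'diagonal'.
    ci_level : float
        Coverage of the reported fixed-effect confidence intervals.

    Fitted attributes (trailing underscore): ``fe_params_`` (b0, b1),
    ``fe_se_``, ``fe_ci_``, ``cov_subject_``, ``cov_eye_``, ``sigma2_``,
    ``blups_`` (DataFrame: eye_id index, subject_id, baseline, slope),
    ``criterion_``, ``converged_``, ``degenerate_``, ``n_eyes_``,
    ``n_subjects_``, ``n_obs_``.
    """

    def __init__(self, method: str = "reml", re_structure: str = "unstructured",
                 ci_level: float = 0.95):
        self.method = method
        self.re_structure = re_structure
        self.ci_level = ci_level

    # -- fitting ---------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None):
        if self.method not in ("reml", "ml"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.re_structure not in ("unstructured", "diagonal"):
            raise ValidationError(f"unknown re_structure {self.re_structure!r}")
        df = _validate_series(pd.DataFrame(X))
        if df["subject_id"].nunique() < 2:
            raise ValidationError("need >= 2 subjects to fit the mixed model")
        self.n_obs_ = len(df)
        self.n_eyes_ = df["eye_id"].nunique()
        self.n_subjects_ = df["subject_id"].nunique()

        ols = ols_oracle(df)
        scale = max(1.0, float(np.var(df["value"])))
        if float(ols["rss"].sum()) / len(df) < DEGENERATE_RTOL * scale:
            self._fit_degenerate(df, ols)
            return self

        self._fit_statsmodels(df, ols)
        return self

    def _fit_degenerate(self, df, ols):
        """Exact zero-residual-variance limit: BLUPs are the per-eye lines."""
        self.degenerate_ = True
        self.sigma2_ = 0.0
        coefs = ols[["intercept", "slope"]]
        subj_of = df.groupby("eye_id")["subject_id"].first()
        subj_mean = coefs.groupby(subj_of).mean()
        fe = subj_mean.mean(axis=0).to_numpy()
        self.fe_params_ = fe.copy()
        dev_subj = subj_mean - fe
        self.cov_subject_ = np.atleast_2d(np.cov(dev_subj.to_numpy().T)) \
            if len(subj_mean) > 1 else np.zeros((2, 2))
        dev_eye = coefs - subj_mean.loc[subj_of.values].to_numpy()
        ve = dev_eye.to_numpy()
        self.cov_eye_ = np.diag(ve.var(axis=0)) if len(ve) > 1 else np.zeros((2, 2))
        se = np.sqrt(np.diag(self.cov_subject_) / max(1, len(subj_mean)))
        self.fe_se_ = se
        z = sps.norm.ppf(0.5 + self.ci_level / 2)
        self.fe_ci_ = np.column_stack([fe - z * se, fe + z * se])
        blups = coefs.rename(columns={"intercept": "baseline"})
        blups["subject_id"] = subj_of
        self.blups_ = blups[["subject_id", "baseline", "slope"]]
        self.criterion_ = float("inf")  # likelihood degenerates as sigma2 -> 0
        self.converged_ = True
        self.re_structure_used_ = self.re_structure
        self.result_ = None

    def _build_model(self, df):
        return sm.MixedLM.from_formula(
            "value ~ time_years", groups="subject_id",
            re_formula="~ time_years",
            vc_formula={"eyeint": "0 + C(eye_id)",
                        "eyeslope": "0 + C(eye_id):time_years"},
            data=df)

    def _diag_free(self):
        return MixedLMParams.from_components(
            fe_params=np.ones(2), cov_re=np.eye(2), vcomp=np.ones(2))

    def _moment_start(self, df, ols, t_mean, y_scale):
        """Method-of-moments starting values on the standardized/centred
        scale, from the per-eye OLS coefficients.  Good starts make the
        profiled criterion surface easy for the optimizers and avoid the
        poor local optima occasionally reported as converged."""
        n_per_eye = df.groupby("eye_id")["value"].count()
        dof = float((n_per_eye - 2).clip(lower=0).sum())
        sigma2 = max(float(ols["rss"].sum()) / max(dof, 1.0), 1e-8 * y_scale ** 2)
        coefs = ols.copy()
        coefs["intercept"] = coefs["intercept"] + coefs["slope"] * t_mean
        c = coefs[["intercept", "slope"]].to_numpy() / y_scale
        sigma2 /= y_scale ** 2
        cov_tot = np.cov(c.T) if len(c) > 1 else np.eye(2)
        cov_tot = np.atleast_2d(cov_tot)
        # split evenly between the two levels; keep strictly positive
        g = 0.5 * cov_tot
        w, v = np.linalg.eigh(g)
        g = (v * np.maximum(w, 1e-4)) @ v.T
        vc = np.maximum(0.5 * np.diag(cov_tot), 1e-4)
        return MixedLMParams.from_components(
            fe_params=c.mean(axis=0), cov_re=g / sigma2, vcomp=vc / sigma2)

    def _fit_statsmodels(self, df, ols):
        self.degenerate_ = False
        reml = self.method == "reml"
        # standardize the response for optimizer conditioning; REML/ML are
        # exactly equivariant under this affine map, so estimates are
        # rescaled back without approximation
        y_mean = float(df["value"].mean())
        y_scale = float(df["value"].std(ddof=0)) or 1.0
        # centre time: random effects are parametrized at the mean follow-up
        # time, where intercept and slope estimates are orthogonal for
        # balanced designs.  For the unstructured covariance this is an
        # exact reparametrization; for the diagonal constraint it is where
        # the independence restriction is imposed (imposing it at t=0 would
        # make the model depend on the arbitrary time origin).  Results are
        # mapped back to the t=0 (baseline) origin afterwards.
        t_mean = float(df["time_years"].mean())
        dfs = df.copy()
        dfs["value"] = (dfs["value"] - y_mean) / y_scale
        dfs["time_years"] = dfs["time_years"] - t_mean
        self._y_mean, self._y_scale, self._t_mean = y_mean, y_scale, t_mean
        model = self._build_model(dfs)
        start = self._moment_start(df, ols, t_mean, y_scale)
        attempts = [self.re_structure]
        if self.re_structure == "unstructured":
            attempts.append("diagonal")
        result, used = None, None
        for structure in attempts:
            free = self._diag_free() if structure == "diagonal" else None
            if structure == "diagonal":
                # the constraint fixes non-free entries at their starting
                # values, so the start must itself be diagonal
                s0 = MixedLMParams.from_components(
                    fe_params=start.fe_params,
                    cov_re=np.diag(np.diag(start.cov_re)),
                    vcomp=start.vcomp)
            else:
                s0 = start
            for opt, sp in (("bfgs", s0), ("lbfgs", s0), ("bfgs", None),
                            ("cg", s0)):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        res = model.fit(reml=reml, free=free, method=opt,
                                        start_params=sp, maxiter=500)
                    except (np.linalg.LinAlgError, ValueError) as exc:
                        logger.warning("mixed-model fit raised under %s/%s: %s",
                                       structure, opt, exc)
                        continue
                if res.converged:
                    if result is None or not result.converged \
                            or res.llf > result.llf:
                        result, used = res, structure
                    break
                result, used = result or res, used or structure  # flagged fallback
            if result is not None and result.converged:
                break
            logger.warning("mixed-model fit did not converge under %s structure",
                           structure)
        if result is None:
            raise NotConvergedError("mixed-model fit failed under all structures")
        if used != attempts[0]:
            logger.info("fell back to %s random-effect structure", used)
        self.result_ = result
        self.re_structure_used_ = used
        self.converged_ = bool(result.converged)
        s, tm = y_scale, t_mean
        # back-transform: value de-standardized, then intercepts moved from
        # the mean-time origin to t=0 via T = [[1, -t_mean], [0, 1]]
        T = np.array([[1.0, -tm], [0.0, 1.0]])
        fe_c = result.fe_params.to_numpy() * s + np.array([y_mean, 0.0])
        self.fe_params_ = T @ fe_c
        try:
            cov_fe_c = np.asarray(result.cov_params())[:2, :2] * s ** 2
            if (not np.all(np.isfinite(cov_fe_c))
                    or np.any(np.diag(cov_fe_c) < 0)):
                raise ValueError("unusable fixed-effect covariance")
        except Exception:  # fall back to marginal SEs (orthogonal at t_mean)
            cov_fe_c = np.diag(np.asarray(result.bse_fe) ** 2) * s ** 2
        cov_fe = T @ cov_fe_c @ T.T
        self.fe_se_ = np.sqrt(np.maximum(np.diag(cov_fe), 0.0))
        z = sps.norm.ppf(0.5 + self.ci_level / 2)
        self.fe_ci_ = np.column_stack([self.fe_params_ - z * self.fe_se_,
                                       self.fe_params_ + z * self.fe_se_])
        self.cov_subject_ = T @ (result.cov_re.to_numpy() * s ** 2) @ T.T
        self.cov_eye_ = T @ (np.diag(result.vcomp) * s ** 2) @ T.T
        self.sigma2_ = float(result.scale) * s ** 2
        # log-likelihood back on the data scale (Jacobian of the affine map;
        # REML contrasts lose p = 2 dimensions).  The REML criterion is
        # invariant under the time recentring (same fixed-effect column
        # space), so only the response scaling enters.
        n_eff = self.n_obs_ - (2 if reml else 0)
        self._llf_offset = -n_eff * np.log(s)
        self.criterion_ = float(result.llf) + self._llf_offset
        blups = self._extract_blups(dfs, result)
        blups["slope"] = s * blups["slope"]
        blups["baseline"] = (y_mean + s * blups["baseline"]
                             - tm * blups["slope"])
        self.blups_ = blups

    _EYE_INT_RE = re.compile(r"eyeint\[C\(eye_id\)\[(.+)\]\]$")
    _EYE_SLOPE_RE = re.compile(r"eyeslope\[C\(eye_id\)\[(.+)\]:time_years\]$")

    def _extract_blups(self, df, result) -> pd.DataFrame:
        # operates on the model's (standardized) scale; caller rescales
        b0, b1 = result.fe_params.to_numpy()
        subj_of = df.groupby("eye_id")["subject_id"].first()
        rows = {}
        for group, ser in result.random_effects.items():
            sub_int = sub_slope = 0.0
            eyes = {}
            for name, val in ser.items():
                m = self._EYE_INT_RE.match(name)
                if m:
                    eyes.setdefault(m.group(1), {})["int"] = val
                    continue
                m = self._EYE_SLOPE_RE.match(name)
                if m:
                    eyes.setdefault(m.group(1), {})["slope"] = val
                    continue
                if "time_years" in name:
                    sub_slope = val
                else:
                    sub_int = val
            for eye, d in eyes.items():
                if subj_of.get(eye) is None:
                    continue  # category level absent from this group
                if str(subj_of[eye]) != str(group):
                    continue
                rows[eye] = (subj_of[eye],
                             b0 + sub_int + d.get("int", 0.0),
                             b1 + sub_slope + d.get("slope", 0.0))
        blups = pd.DataFrame.from_dict(
            rows, orient="index", columns=["subject_id", "baseline", "slope"])
        blups.index.name = "eye_id"
        return blups.sort_index()

    # -- post-fit utilities ---------------------------------------------
    def criterion_at(self, packed_cov_params: np.ndarray) -> float:
        """Evaluate the fit criterion at alternative covariance parameters.

        ``packed_cov_params`` replaces the packed random-effect parameter
        vector (statsmodels' internal parametrization, no fixed effects);
        used for local-optimality checks.
        """
        if self.result_ is None:
            raise NotConvergedError("no statsmodels result available")
        params = MixedLMParams.from_packed(
            np.asarray(packed_cov_params, dtype=float), k_fe=2, k_re=2,
            use_sqrt=False, has_fe=False)
        return float(self.result_.model.loglike(params, profile_fe=True)) \
            + self._llf_offset

    @property
    def packed_cov_params_(self) -> np.ndarray:
        if self.result_ is None:
            raise NotConvergedError("no statsmodels result available")
        po = self.result_.params_object
        return po.get_packed(use_sqrt=False, has_fe=False)


# ---------------------------------------------------------------------------
# functional wrappers

@dataclass
class LmmFit:
    """Fitted model summary: fixed effects, variance components, BLUPs."""

    beta: np.ndarray              # (b0, b1)
    se: np.ndarray
    ci: np.ndarray                # 2x2, rows (b0, b1), cols (lo, hi)
    cov_subject: np.ndarray
    cov_eye: np.ndarray
    sigma2: float
    blups: pd.DataFrame
    criterion: float
    converged: bool
    degenerate: bool
    re_structure_used: str
    n_eyes: int
    n_subjects: int
    n_obs: int
    label: dict = field(default_factory=dict)

    @property
    def beta0(self) -> float:
        return float(self.beta[0])

    @property
    def beta1(self) -> float:
        return float(self.beta[1])


def fit_lmm(series: pd.DataFrame, method: str = "reml",
            re_structure: str = "unstructured", label: dict | None = None) -> LmmFit:
    """Fit the nested random-slope model to one long-format outcome series."""
    est = RandomSlopeLMM(method=method, re_structure=re_structure).fit(series)
    return LmmFit(
        beta=est.fe_params_, se=est.fe_se_, ci=est.fe_ci_,
        cov_subject=est.cov_subject_, cov_eye=est.cov_eye_,
        sigma2=est.sigma2_, blups=est.blups_, criterion=est.criterion_,
        converged=est.converged_, degenerate=est.degenerate_,
        re_structure_used=est.re_structure_used_, n_eyes=est.n_eyes_,
        n_subjects=est.n_subjects_, n_obs=est.n_obs_, label=dict(label or {}))


def extract_blups(fit: LmmFit) -> pd.DataFrame:
    """Per-eye (baseline, slope) BLUP table from a converged fit."""
    if not fit.converged:
        raise NotConvergedError(
            "refusing BLUPs from a non-converged fit; refit with "
            "re_structure='diagonal' or inspect the data")
    return fit.blups.copy()
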