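"""Nested random-effects variance analysis of repeated-survey heights.

Repeated AUV surveys of the same ground yield shell-height measurements
grouped as observations within frames, frames within transects and
transects within surveys.  The model is the Gaussian nested
random-intercept model

    y_ijkl = mu + s_i + t_j(i) + f_k(ij) + e_ijkl,

with independent zero-mean effects of variances sigma2_survey,
sigma2_transect, sigma2_frame and residual sigma2_resid.  All five
parameters are estimated by maximum likelihood (not REML, so that
likelihood-ratio comparisons between nested models are valid), and the
survey effect is tested by comparing the full model against a reduced
model without the survey term: twice the log-likelihood difference
referred to chi-square with 1 df.  Because the null value sits on the
boundary of the parameter space this reference distribution is
conservative; the 50:50 chi-bar-square mixture is available via
``boundary_mixture=True``.

The log-likelihood is evaluated exactly in O(n) by collapsing the
hierarchy level by level: marginalizing a level's random intercept over
a group whose members have variances v_i turns the group into a single
pseudo-observation (its precision-weighted mean, with variance
1/sum(1/v_i) + tau) plus a closed-form "within" contribution.  This is
algebraically identical to the dense multivariate-normal density with
the full nested covariance matrix (tested against it), but linear in
the number of observations and valid for arbitrarily unbalanced
designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConvergenceError, UnderdeterminedFitError

__all__ = [
    "NestedDesign",
    "NestedModelFit",
    "LRTResult",
    "nested_log_likelihood",
    "fit_nested_model",
    "lrt_survey_effect",
    "variance_report",
    "aic",
    "bic",
    "comparison_table",
]

_LOG2PI = math.log(2.0 * math.pi)
_VARIANCE_FLOOR = 1e-12  # fitted components below this are reported as 0


@dataclass(frozen=True)
class NestedDesign:
    """Pre-factorized grouping structure of a measurement table."""

    y: np.ndarray                   # (n,) heights, cm
    frame_of_obs: np.ndarray        # (n,) codes 0..n_frames-1
    transect_of_frame: np.ndarray   # (n_frames,) codes 0..n_transects-1
    survey_of_transect: np.ndarray  # (n_transects,) codes 0..n_surveys-1
    n_frames: int
    n_transects: int
    n_surveys: int

    @classmethod
    def from_frame(
        cls, records: pd.DataFrame, height_col: str = "height_cm"
    ) -> "NestedDesign":
        """Build the design from survey_id/transect_id/frame_id columns.

        Transect and frame labels are interpreted hierarchically, so a
        transect label reused across surveys denotes distinct transects.
        """
        for col in ("survey_id", "transect_id", "frame_id"):
            if col not in records.columns:
                raise UnderdeterminedFitError(f"missing grouping column {col}")
            if records[col].isna().any() or (records[col].astype(str) == "").any():
                raise UnderdeterminedFitError(f"empty ids in column {col}")
        y = records[height_col].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise UnderdeterminedFitError("heights must be finite")
        if np.any(y <= 0):
            raise UnderdeterminedFitError("heights must be > 0")
        s = records["survey_id"].astype(str).to_numpy()
        t = np.char.add(np.char.add(s, ":"),
                        records["transect_id"].astype(str).to_numpy())
        f = np.char.add(np.char.add(t, ":"),
                        records["frame_id"].astype(str).to_numpy())
        f_codes, f_keys = pd.factorize(f, sort=True)
        # map each frame to its transect, each transect to its survey
        first_obs_of_frame = np.zeros(len(f_keys), dtype=int)
        first_obs_of_frame[f_codes[::-1]] = np.arange(len(f_codes))[::-1]
        t_of_frame_lbl = t[first_obs_of_frame]
        t_codes_frame, t_keys = pd.factorize(t_of_frame_lbl, sort=True)
        first_frame_of_t = np.zeros(len(t_keys), dtype=int)
        first_frame_of_t[t_codes_frame[::-1]] = np.arange(len(t_codes_frame))[::-1]
        s_of_t_lbl = s[first_obs_of_frame[first_frame_of_t]]
        s_codes_t, s_keys = pd.factorize(s_of_t_lbl, sort=True)
        return cls(
            y=y,
            frame_of_obs=f_codes,
            transect_of_frame=t_codes_frame,
            survey_of_transect=s_codes_t,
            n_frames=len(f_keys),
            n_transects=len(t_keys),
            n_surveys=len(s_keys),
        )

    @property
    def n_obs(self) -> int:
        return len(self.y)


@dataclass(frozen=True)
class NestedModelFit:
    """ML fit of the nested model (variances in cm^2)."""

    mu: float
    sigma2_survey: float
    sigma2_transect: float
    sigma2_frame: float
    sigma2_resid: float
    include_survey: bool
    log_likelihood: float
    n_params: int
    n_obs: int
    converged: bool


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio comparison of full vs no-survey-effect models."""

    statistic: float
    df: int
    p_value: float
    aic_full: float
    aic_reduced: float
    bic_full: float
    bic_reduced: float
    fit_full: NestedModelFit
    fit_reduced: NestedModelFit


def _collapse(y, v, codes, n_groups, tau):
    """Marginalize one hierarchy level.

    Members ``y`` with variances ``v`` in groups ``codes`` collapse to
    per-group precision-weighted means with variance 1/W + tau, plus the
    closed-form log-density contribution of the within-group directions.
    """
    w = 1.0 / v
    W = np.bincount(codes, weights=w, minlength=n_groups)
    m = np.bincount(codes, weights=w * y, minlength=n_groups) / W
    r = y - m[codes]
    z = np.bincount(codes, weights=w * r * r, minlength=n_groups)
    cnt = np.bincount(codes, minlength=n_groups)
    logv = np.bincount(codes, weights=np.log(v), minlength=n_groups)
    contrib = -0.5 * float(
        np.sum((cnt - 1) * _LOG2PI + logv + np.log(W) + z)
    )
    return m, 1.0 / W + tau, contrib


def _collapse_obs(y, sigma2_resid, codes, n_groups, tau):
    """Observation-level collapse with a common residual variance."""
    cnt = np.bincount(codes, minlength=n_groups)
    m = np.bincount(codes, weights=y, minlength=n_groups) / cnt
    r = y - m[codes]
    ss = np.bincount(codes, weights=r * r, minlength=n_groups)
    contrib = -0.5 * float(
        np.sum(
            (cnt - 1) * (_LOG2PI + math.log(sigma2_resid))
            + np.log(cnt)
            + ss / sigma2_resid
        )
    )
    return m, sigma2_resid / cnt + tau, contrib


def _profile_chain(design: NestedDesign, s2_s, s2_t, s2_f, s2_e):
    """Collapse the full hierarchy; return survey-level pseudo-obs
    (means, variances) and the accumulated within contribution."""
    m, v, c1 = _collapse_obs(
        design.y, s2_e, design.frame_of_obs, design.n_frames, s2_f
    )
    m, v, c2 = _collapse(
        m, v, design.transect_of_frame, design.n_transects, s2_t
    )
    m, v, c3 = _collapse(
        m, v, design.survey_of_transect, design.n_surveys, s2_s
    )
    return m, v, c1 + c2 + c3


def nested_log_likelihood(
    records: pd.DataFrame | NestedDesign,
    mu: float,
    sigma2_survey: float,
    sigma2_transect: float,
    sigma2_frame: float,
    sigma2_resid: float,
    height_col: str = "height_cm",
) -> float:
    """Exact Gaussian log-likelihood of the nested random-intercept model.

    Equals the dense multivariate-normal log-density with covariance
    built from the nested grouping, evaluated in O(n).  Variance
    components must be >= 0 and the residual variance > 0.
    """
    for name, v in (
        ("sigma2_survey", sigma2_survey),
        ("sigma2_transect", sigma2_transect),
        ("sigma2_frame", sigma2_frame),
        ("sigma2_resid", sigma2_resid),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    if sigma2_resid <= 0:
        raise ValueError("sigma2_resid must be > 0")
    design = (
        records
        if isinstance(records, NestedDesign)
        else NestedDesign.from_frame(records, height_col)
    )
    m, v, within = _profile_chain(
        design, sigma2_survey, sigma2_transect, sigma2_frame, sigma2_resid
    )
    top = -0.5 * float(np.sum(np.log(2.0 * np.pi * v) + (m - mu) ** 2 / v))
    return within + top


def _moment_start(design: NestedDesign) -> np.ndarray:
    """Crude method-of-moments variance components for optimizer starts."""
    y = design.y
    total_var = max(float(np.var(y)), 1e-8)
    floor = max(1e-4 * total_var, 1e-10)
    cnt_f = np.bincount(design.frame_of_obs, minlength=design.n_frames)
    m_f = np.bincount(design.frame_of_obs, weights=y,
                      minlength=design.n_frames) / cnt_f
    within = y - m_f[design.frame_of_obs]
    dof = max(design.n_obs - design.n_frames, 1)
    s2_e = max(float(np.sum(within**2)) / dof, floor)
    mean_nf = design.n_obs / design.n_frames
    s2_f = max(float(np.var(m_f)) - s2_e / mean_nf, floor)
    cnt_t = np.bincount(design.transect_of_frame, minlength=design.n_transects)
    m_t = np.bincount(design.transect_of_frame, weights=m_f,
                      minlength=design.n_transects) / cnt_t
    s2_t = max(float(np.var(m_t)) - s2_f / max(cnt_t.mean(), 1.0), floor)
    cnt_s = np.bincount(design.survey_of_transect, minlength=design.n_surveys)
    m_s = np.bincount(design.survey_of_transect, weights=m_t,
                      minlength=design.n_surveys) / cnt_s
    s2_s = max(float(np.var(m_s)) - s2_t / max(cnt_s.mean(), 1.0), floor)
    return np.array([s2_s, s2_t, s2_f, s2_e])


def fit_nested_model(
    records: pd.DataFrame | NestedDesign,
    include_survey: bool = True,
    height_col: str = "height_cm",
    n_starts: int = 5,
    seed: int = 0,
) -> NestedModelFit:
    """Maximum-likelihood fit of the nested model.

    Optimizes the variance components in log space (Nelder-Mead,
    multi-start: a method-of-moments start plus jittered copies) with
    the grand mean profiled out as the generalized-least-squares mean.
    Components that converge to the boundary (< 1e-12) are reported as
    exactly 0.  The reduced model (``include_survey=False``) fixes the
    survey component at 0 but keeps surveys in the nesting of labels.
    """
    design = (
        records
        if isinstance(records, NestedDesign)
        else NestedDesign.from_frame(records, height_col)
    )
    if include_survey and design.n_surveys < 2:
        raise UnderdeterminedFitError(
            f">= 2 surveys required to estimate a survey effect, got "
            f"{design.n_surveys}"
        )
    if design.n_transects < 2 or design.n_frames < 2:
        raise UnderdeterminedFitError(
            ">= 2 transects and >= 2 frames required"
        )
    n_params = 5 if include_survey else 4

    if np.ptp(design.y) == 0:
        # degenerate data: all heights identical; the Gaussian likelihood
        # is unbounded as variances -> 0, the natural fit is exact.
        return NestedModelFit(
            mu=float(design.y[0]),
            sigma2_survey=0.0, sigma2_transect=0.0,
            sigma2_frame=0.0, sigma2_resid=0.0,
            include_survey=include_survey,
            log_likelihood=math.inf,
            n_params=n_params, n_obs=design.n_obs, converged=True,
        )

    k = 4 if include_survey else 3  # free variance components

    def unpack(x):
        v = np.exp(np.clip(x, -40.0, 40.0))
        if include_survey:
            return v[0], v[1], v[2], v[3]
        return 0.0, v[0], v[1], v[2]

    def negloglik(x):
        s2_s, s2_t, s2_f, s2_e = unpack(x)
        m, v, within = _profile_chain(design, s2_s, s2_t, s2_f, s2_e)
        w = 1.0 / v
        mu_hat = float(np.sum(w * m) / np.sum(w))
        top = -0.5 * float(
            np.sum(np.log(2.0 * np.pi * v) + (m - mu_hat) ** 2 * w)
        )
        return -(within + top)

    start = np.log(_moment_start(design))
    if not include_survey:
        start = start[1:]
    rng = np.random.default_rng(seed)
    starts = [start] + [
        start + rng.normal(0.0, 1.0, size=k) for _ in range(n_starts - 1)
    ]

    best_x, best_nll, any_ok = None, math.inf, False
    for x0 in starts:
        res = optimize.minimize(
            negloglik, x0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-9, "maxiter": 4000,
                     "maxfev": 6000},
        )
        if np.isfinite(res.fun):
            any_ok = any_ok or bool(res.success)
            if res.fun < best_nll:
                best_nll, best_x = float(res.fun), res.x
    if best_x is None or not any_ok:
        raise ConvergenceError(
            "nested-model likelihood optimization failed from every start",
            diagnostics={"n_starts": len(starts), "n_obs": design.n_obs},
        )

    s2_s, s2_t, s2_f, s2_e = unpack(best_x)
    s2_s = 0.0 if s2_s < _VARIANCE_FLOOR else s2_s
    s2_t = 0.0 if s2_t < _VARIANCE_FLOOR else s2_t
    s2_f = 0.0 if s2_f < _VARIANCE_FLOOR else s2_f
    m, v, within = _profile_chain(design, s2_s, s2_t, s2_f, s2_e)
    w = 1.0 / v
    mu_hat = float(np.sum(w * m) / np.sum(w))
    ll = within - 0.5 * float(
        np.sum(np.log(2.0 * np.pi * v) + (m - mu_hat) ** 2 * w)
    )
    return NestedModelFit(
        mu=mu_hat,
        sigma2_survey=s2_s, sigma2_transect=s2_t,
        sigma2_frame=s2_f, sigma2_resid=s2_e,
        include_survey=include_survey,
        log_likelihood=ll,
        n_params=n_params, n_obs=design.n_obs, converged=True,
    )


def aic(fit: NestedModelFit) -> float:
    """Akaike information criterion, -2*logLik + 2*k."""
    return -2.0 * fit.log_likelihood + 2.0 * fit.n_params


def bic(fit: NestedModelFit) -> float:
    """Bayesian information criterion, -2*logLik + k*ln(n)."""
    return -2.0 * fit.log_likelihood + fit.n_params * math.log(fit.n_obs)


def lrt_p_value(statistic: float, boundary_mixture: bool = False) -> float:
    """Upper-tail p of the survey-effect LRT statistic.

    Default: chi-square with 1 df (the conventional reference, which is
    conservative when the null variance sits on the boundary).  With
    ``boundary_mixture=True``: the 50:50 mixture of a point mass at 0
    and chi-square(1).
    """
    if statistic < 0:
        raise ValueError("LRT statistic must be >= 0")
    if not boundary_mixture:
        return float(stats.chi2.sf(statistic, df=1))
    return 1.0 if statistic == 0 else float(0.5 * stats.chi2.sf(statistic, 1))


def lrt_survey_effect(
    records: pd.DataFrame | NestedDesign,
    boundary_mixture: bool = False,
    height_col: str = "height_cm",
    n_starts: int = 5,
    seed: int = 0,
) -> LRTResult:
    """Test the survey variance component by likelihood ratio.

    Fits the full (survey + transect + frame) and reduced (transect +
    frame) models by ML and compares twice the log-likelihood gain to
    chi-square(1) (or the boundary mixture).
    """
    design = (
        records
        if isinstance(records, NestedDesign)
        else NestedDesign.from_frame(records, height_col)
    )
    full = fit_nested_model(design, include_survey=True,
                            n_starts=n_starts, seed=seed)
    reduced = fit_nested_model(design, include_survey=False,
                               n_starts=n_starts, seed=seed)
    statistic = max(
        0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood)
    )
    return LRTResult(
        statistic=statistic,
        df=full.n_params - reduced.n_params,
        p_value=lrt_p_value(statistic, boundary_mixture),
        aic_full=aic(full), aic_reduced=aic(reduced),
        bic_full=bic(full), bic_reduced=bic(reduced),
        fit_full=full, fit_reduced=reduced,
    )


def variance_report(fit: NestedModelFit) -> pd.DataFrame:
    """Variance components with their proportions of the total."""
    comps = {
        "survey": fit.sigma2_survey,
        "transect_in_survey": fit.sigma2_transect,
        "frame": fit.sigma2_frame,
        "residual": fit.sigma2_resid,
    }
    total = sum(comps.values())
    return pd.DataFrame(
        {
            "component": list(comps),
            "variance_cm2": list(comps.values()),
            "proportion": [
                v / total if total > 0 else 0.0 for v in comps.values()
            ],
        }
    )


def comparison_table(result: LRTResult) -> pd.DataFrame:
    """Model-comparison table analogous to an anova() printout:
    reduced model first, then the full model with the LRT columns."""
    return pd.DataFrame(
        {
            "model": ["reduced (no survey)", "full"],
            "Df": [result.fit_reduced.n_params, result.fit_full.n_params],
            "AIC": [result.aic_reduced, result.aic_full],
            "BIC": [result.bic_reduced, result.bic_full],
            "logLik": [
                result.fit_reduced.log_likelihood,
                result.fit_full.log_likelihood,
            ],
            "Chisq": [np.nan, result.statistic],
            "Chi Df": [np.nan, result.df],
            "Pr(>Chisq)": [np.nan, result.p_value],
        }
    )
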