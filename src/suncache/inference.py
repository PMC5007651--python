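"""Regression layer: linear mixed models with subject-nested-in-group
random intercepts and likelihood-ratio tests for fixed effects.

Backed by :mod:`statsmodels` ``MixedLM`` (the modelling machinery is
standard; the substance of this pipeline lives in the solar/angular
modules).  All LRT comparisons are between ML fits, since REML likelihoods
are not comparable across fixed-effect structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidComparisonError, InvalidInputError

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = ["ModelSpec", "FittedLMM", "LRTResult", "fit_lmm", "lrt", "paper_model_suite"]


@dataclass(frozen=True)
class ModelSpec:
    response: str
    fixed: tuple = ()
    subject_col: str = "subject_id"
    group_col: str = "group_id"
    method: str = "ML"  # or "REML"

    def formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        return f"{self.response} ~ {rhs}"


@dataclass
class FittedLMM:
    spec: ModelSpec
    result: object  # statsmodels MixedLMResults
    loglik: float
    k_fixed: int
    n_obs: int
    singular: bool
    warnings: list = field(default_factory=list)

    @property
    def coefficients(self) -> dict:
        return dict(self.result.fe_params)

    def coef_se(self) -> dict:
        return dict(self.result.bse_fe)


@dataclass(frozen=True)
class LRTResult:
    chi2: float
    df: int
    p: float
    loglik_full: float
    loglik_reduced: float


#: optimizers tried for every fit; the best finite log-likelihood wins.
#: lbfgs is excluded: it intermittently reports spurious infinite
#: likelihoods on boundary fits.
DEFAULT_OPTIMIZERS = ("powell", "nm")


def fit_lmm(data: pd.DataFrame, spec: ModelSpec,
            optimizers=DEFAULT_OPTIMIZERS) -> FittedLMM:
    """Fit an LMM with random intercepts for group and subject-in-group.

    If the data contain a single group (or the group column is absent),
    the structure degrades gracefully to a subject-level random intercept.
    Singular fits (a variance component estimated at zero) are flagged, not
    fatal.  Each optimizer in ``optimizers`` is run and the best finite
    log-likelihood is kept (profiled mixed likelihoods are multimodal
    enough for single-optimizer fits to corrupt LRTs).
    """
    needed = [spec.response, *[c for c in spec.fixed if c in data.columns or "C(" not in c]]
    for col in [spec.response]:
        if col not in data.columns:
            raise InvalidInputError(f"response column {col!r} missing")
    df = data.dropna(subset=[c for c in needed if c in data.columns]).copy()
    if len(df) < 3:
        raise InvalidInputError("too few rows for a mixed model")
    if float(np.std(df[spec.response].to_numpy(float))) == 0.0:
        raise InvalidInputError(
            f"response {spec.response!r} is constant: zero residual variance"
        )

    has_group = spec.group_col in df.columns and df[spec.group_col].nunique() > 1
    has_subject = (spec.subject_col != spec.group_col
                   and spec.subject_col in df.columns
                   and df[spec.subject_col].nunique() > 1)

    caught: list = []
    result = None
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        if has_group:
            vc = {}
            if has_subject:
                vc["subject"] = f"0 + C({spec.subject_col})"
            model = smf.mixedlm(
                spec.formula(), df, groups=df[spec.group_col],
                re_formula="1", vc_formula=vc or None,
            )
        elif has_subject:
            model = smf.mixedlm(spec.formula(), df, groups=df[spec.subject_col], re_formula="1")
        else:
            raise InvalidInputError("need at least 2 groups or 2 subjects for random effects")
        reml = spec.method.upper() == "REML"
        for meth in optimizers:
            try:
                cand = model.fit(reml=reml, method=[meth])
            except (np.linalg.LinAlgError, ValueError):
                continue
            if not np.isfinite(cand.llf):
                continue
            if result is None or cand.llf > result.llf:
                result = cand
        if result is None:
            raise InvalidInputError("all optimizers failed to produce a finite likelihood")
        caught = [str(w.message) for w in wrec if issubclass(w.category, (ConvergenceWarning, UserWarning, RuntimeWarning))]

    vcomp = np.concatenate([np.atleast_1d(np.diag(np.atleast_2d(result.cov_re))),
                            np.atleast_1d(result.vcomp) if result.vcomp.size else np.array([])])
    singular = bool(np.any(vcomp < 1e-10)) or result.scale < 1e-12
    return FittedLMM(
        spec=spec,
        result=result,
        loglik=float(result.llf),
        k_fixed=int(len(result.fe_params)),
        n_obs=int(result.nobs),
        singular=singular,
        warnings=caught,
    )


def lrt(full: FittedLMM, reduced: FittedLMM) -> LRTResult:
    """Likelihood-ratio test of nested ML fits on identical rows."""
    if full.spec.method.upper() != "ML" or reduced.spec.method.upper() != "ML":
        raise InvalidComparisonError("LRT requires ML (not REML) fits")
    if full.n_obs != reduced.n_obs:
        raise InvalidComparisonError(
            f"fits use different row counts: {full.n_obs} vs {reduced.n_obs}"
        )
    df = full.k_fixed - reduced.k_fixed
    if df <= 0:
        raise InvalidComparisonError("reduced model must have fewer fixed-effect terms")
    red_terms = set(reduced.result.fe_params.index)
    full_terms = set(full.result.fe_params.index)
    if not red_terms <= full_terms:
        raise InvalidComparisonError("models are not nested in their fixed effects")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return LRTResult(
        chi2=chi2, df=df, p=float(stats.chi2.sf(chi2, df)),
        loglik_full=full.loglik, loglik_reduced=reduced.loglik,
    )


def _fixed_effect_lrt(df: pd.DataFrame, response: str, term: str,
                      subject_col="subject_id", group_col="group_id") -> dict:
    full = fit_lmm(df, ModelSpec(response, (term,), subject_col, group_col))
    reduced = fit_lmm(df, ModelSpec(response, (), subject_col, group_col))
    r = lrt(full, reduced)
    out = {
        "n": full.n_obs,
        "coefficients": {k: float(v) for k, v in full.coefficients.items()},
        "chi2": r.chi2, "df": r.df, "p": r.p,
        "singular": full.singular or reduced.singular,
    }
    return out


def _signed_deg(az: pd.Series) -> pd.Series:
    """Azimuth wrapped to (-180, 180]; continuous across north."""
    return -(((-az + 180.0) % 360.0) - 180.0)


def paper_model_suite(tracks: pd.DataFrame | None = None,
                      classifications: pd.DataFrame | None = None,
                      events: pd.DataFrame | None = None,
                      areas: pd.DataFrame | None = None,
                      component_assignment: pd.Series | None = None) -> dict:
    """Run the named mixed-model analyses of the pipeline; each entry is a
    fixed-effect LRT (or a skip record when its inputs are unavailable).

    Models:
      a. absolute track direction ~ solar azimuth (both signed degrees;
         the track direction is the toward-sun-folded bearing so that the
         response is continuous across the solar arc)
      b. reflected offset angle ~ observation period (categorical)
      c. per-component mean offset vs zero
      d. time-to-theft (h) ~ group size, stolen caches
      e. group size ~ recovery category
      f. recovery azimuth ~ cache azimuth (signed degrees)
      g. azimuthal recovery error ~ solar elevation at caching
      h. azimuthal recovery error ~ recovery category
      i. hull area vs null circular area (paired, per subject)
    """
    report: dict = {}

    def _skip(name, reason):
        report[name] = {"skipped": True, "reason": reason}

    def _run(name, fn):
        try:
            report[name] = fn()
            report[name]["skipped"] = False
        except (InvalidInputError, InvalidComparisonError, KeyError, ValueError,
                np.linalg.LinAlgError) as exc:
            _skip(name, f"{type(exc).__name__}: {exc}")

    # --- track-angle models -------------------------------------------------
    if tracks is not None and len(tracks):
        tr = tracks[tracks.get("angle_ok", True) == True].copy()  # noqa: E712

        def model_a():
            d = tr.copy()
            d["sun_signed"] = _signed_deg(d["sun_azimuth_deg"])
            d["track_signed"] = d["sun_signed"] + np.degrees(d["reflected_rad"])
            return _fixed_effect_lrt(d, "track_signed", "sun_signed")

        def model_b():
            if "obs_period" not in tr.columns:
                raise InvalidInputError("tracks table lacks obs_period")
            d = tr.dropna(subset=["obs_period"]).copy()
            d["obs_period"] = d["obs_period"].astype(str)
            if d["obs_period"].nunique() < 2:
                raise InvalidInputError("need >= 2 observation periods")
            full = fit_lmm(d, ModelSpec("reflected_rad", ("C(obs_period)",)))
            reduced = fit_lmm(d, ModelSpec("reflected_rad", ()))
            r = lrt(full, reduced)
            return {"n": full.n_obs, "chi2": r.chi2, "df": r.df, "p": r.p,
                    "singular": full.singular or reduced.singular,
                    "coefficients": {k: float(v) for k, v in full.coefficients.items()}}

        def model_c():
            if component_assignment is None:
                raise InvalidInputError("no component assignment supplied")
            d = tr.copy()
            d["component"] = np.asarray(component_assignment)
            out = {}
            for comp in (1, 2):
                sub = d[d["component"] == comp]
                if len(sub) < 5:
                    out[f"component_{comp}"] = {"skipped": True, "reason": "too few points"}
                    continue
                fit = fit_lmm(sub, ModelSpec("reflected_rad", ()))
                est = fit.coefficients.get("Intercept", np.nan)
                se = fit.coef_se().get("Intercept", np.nan)
                t = est / se if se and np.isfinite(se) and se > 0 else np.nan
                out[f"component_{comp}"] = {
                    "n": fit.n_obs, "mean": float(est), "se": float(se),
                    "t": float(t),
                    "p": float(2 * stats.t.sf(abs(t), fit.n_obs - 1)) if np.isfinite(t) else np.nan,
                    "singular": fit.singular,
                }
            return out

        _run("a_track_vs_sun", model_a)
        _run("b_offset_vs_period", model_b)
        _run("c_component_means_vs_zero", model_c)
    else:
        for name in ("a_track_vs_sun", "b_offset_vs_period", "c_component_means_vs_zero"):
            _skip(name, "tracks table unavailable")

    # --- cache-fate models --------------------------------------------------
    if events is not None and len(events):
        def model_d():
            d = events.query("outcome == 'stolen'").dropna(subset=["event_time_utc"]).copy()
            if len(d) < 5:
                raise InvalidInputError("too few stolen caches")
            lag = (pd.to_datetime(d["event_time_utc"], utc=True)
                   - pd.to_datetime(d["cache_time_utc"], utc=True))
            d["survival_h"] = lag.dt.total_seconds() / 3600.0
            d["group_size"] = d["group_size"].astype(float)
            return _fixed_effect_lrt(d, "survival_h", "group_size")

        _run("d_survival_vs_group_size", model_d)
    else:
        _skip("d_survival_vs_group_size", "events table unavailable")

    if classifications is not None and len(classifications):
        cl = classifications[classifications["category"].isin(["A24", "PRE24"])].copy()

        def model_e():
            d = cl.dropna(subset=["group_size"]).copy()
            d["group_size"] = d["group_size"].astype(float)
            d["is_pre24"] = (d["category"] == "PRE24").astype(float)
            return _fixed_effect_lrt(d, "group_size", "is_pre24")

        def model_f():
            d = cl.copy()
            d["az_cache_signed"] = _signed_deg(d["az_cache_deg"])
            d["az_rec_signed"] = _signed_deg(d["az_recovery_deg"])
            # put PRE24 recoveries on the cache side of the arc so the
            # association is measured on a common (mirror-folded) scale
            flip = d["category"] == "PRE24"
            d.loc[flip, "az_rec_signed"] = -d.loc[flip, "az_rec_signed"]
            return _fixed_effect_lrt(d, "az_rec_signed", "az_cache_signed")

        def model_g():
            return _fixed_effect_lrt(cl, "az_error_deg", "elevation_at_cache_deg")

        def model_h():
            d = cl.copy()
            d["is_pre24"] = (d["category"] == "PRE24").astype(float)
            return _fixed_effect_lrt(d, "az_error_deg", "is_pre24")

        _run("e_group_size_vs_category", model_e)
        _run("f_recovery_vs_cache_azimuth", model_f)
        _run("g_error_vs_elevation", model_g)
        _run("h_error_vs_category", model_h)
    else:
        for name in ("e_group_size_vs_category", "f_recovery_vs_cache_azimuth",
                     "g_error_vs_elevation", "h_error_vs_category"):
            _skip(name, "classification table unavailable")

    # --- area model ---------------------------------------------------------
    if areas is not None and len(areas):
        def model_i():
            d = areas[~areas.get("degenerate", False).astype(bool)]
            if len(d) < 2:
                raise InvalidInputError("too few subjects with valid areas")
            long = pd.concat([
                pd.DataFrame({"subject_id": d["subject_id"], "area": d["hull_area_m2"],
                              "is_null_area": 0.0}),
                pd.DataFrame({"subject_id": d["subject_id"], "area": d["null_area_m2"],
                              "is_null_area": 1.0}),
            ], ignore_index=True)
            full = fit_lmm(long, ModelSpec("area", ("is_null_area",),
                                           subject_col="subject_id", group_col="subject_id"))
            reduced = fit_lmm(long, ModelSpec("area", (),
                                              subject_col="subject_id", group_col="subject_id"))
            r = lrt(full, reduced)
            return {"n_subjects": int(len(d)), "chi2": r.chi2, "df": r.df, "p": r.p,
                    "mean_pct_covered": float(d["pct_covered"].mean()),
                    "sd_pct_covered": float(d["pct_covered"].std(ddof=1)) if len(d) > 1 else np.nan,
                    "coefficients": {k: float(v) for k, v in full.coefficients.items()}}

        _run("i_hull_vs_null_area", model_i)
    else:
        _skip("i_hull_vs_null_area", "area table unavailable")

    return report
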