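"""Mixed-effects models and design/power utilities for the crossover study.

The study design is a balanced single-blinded crossover: every scorer
annotates every seizure under both density conditions (scorers x seizures
x 2 observations). Outcomes — log annotated area, Likert confidence, and
pairwise kappa — are analysed with linear mixed models carrying crossed
random intercepts for scorer and seizure (modelled as uncorrelated), fit by
REML with Wald z confidence intervals.

Models
------
* area:        ``log_area ~ density + multifocal + overlaps_clinical + confidence``
* confidence:  ``confidence ~ density + multifocal + overlaps_clinical + scorer_mean_kappa``
* kappa:       ``kappa ~ density`` with random intercepts for scorer pair and seizure
* carryover:   any of the above refit with the first-shown condition as an
               extra fixed effect

Percent interpretation of a log-scale coefficient: a density coefficient
``b`` on log area means HD annotations are ``100 * (exp(b) - 1)`` percent
larger than LD on average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.power import TTestIndPower

__all__ = [
    "LMMResult",
    "InferenceError",
    "fit_area_model",
    "fit_confidence_model",
    "fit_kappa_model",
    "add_carryover",
    "percent_change_from_log_coef",
    "effective_sample_size",
    "min_detectable_effect",
    "validate_score_table",
]

SCORE_COLUMNS = [
    "scorer_id", "seizure_id", "condition", "order_first", "area_px",
    "log_area", "confidence", "multifocal", "overlaps_clinical",
    "scorer_mean_kappa",
]


class InferenceError(ValueError):
    pass


@dataclass(frozen=True)
class LMMResult:
    """Fixed effects with Wald inference plus variance components."""

    names: tuple[str, ...]
    estimates: np.ndarray
    std_errors: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    vc_scorer: float
    vc_seizure: float
    resid_var: float
    converged: bool
    method: str = "MixedLM-REML"
    warnings_: tuple[str, ...] = field(default=())

    def coef(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def ci(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.ci_low[i]), float(self.ci_high[i])

    def p(self, name: str) -> float:
        return float(self.p_values[self.names.index(name)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(estimate=self.estimates, se=self.std_errors,
                 ci_low=self.ci_low, ci_high=self.ci_high, p=self.p_values),
            index=list(self.names),
        )

    def to_dict(self) -> dict:
        return dict(
            fixed_effects={
                n: dict(estimate=float(e), se=float(s), ci=[float(lo), float(hi)],
                        p=float(p))
                for n, e, s, lo, hi, p in zip(
                    self.names, self.estimates, self.std_errors,
                    self.ci_low, self.ci_high, self.p_values)
            },
            vc_scorer=self.vc_scorer, vc_seizure=self.vc_seizure,
            resid_var=self.resid_var, converged=self.converged,
            method=self.method,
        )


def validate_score_table(t: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format score table and add derived columns.

    One row per scorer x seizure x condition; ``log_area`` is filled from
    ``area_px`` when absent. Rows with non-positive area are rejected (the
    log transform is undefined there).
    """
    t = t.copy()
    required = {"scorer_id", "seizure_id", "condition"}
    missing = required - set(t.columns)
    if missing:
        raise InferenceError(f"score table missing columns: {sorted(missing)}")
    if "area_px" in t.columns:
        bad = t.index[t["area_px"] <= 0].tolist()
        if bad:
            raise InferenceError(f"non-positive area_px in rows {bad}")
        if "log_area" not in t.columns:
            t["log_area"] = np.log(t["area_px"].astype(float))
    dup = t.duplicated(["scorer_id", "seizure_id", "condition"])
    if dup.any():
        raise InferenceError("duplicate scorer x seizure x condition rows")
    t["density"] = (t["condition"].astype(str) == "HD").astype(int)
    if "order_first" in t.columns:
        t["hd_first"] = (t["order_first"].astype(str) == "HD").astype(int)
    return t


def _check_not_constant(t: pd.DataFrame, cols: list[str]) -> None:
    for c in cols:
        if t[c].nunique() < 2:
            raise InferenceError(
                f"predictor {c!r} is constant: coefficient inestimable "
                "(rank-deficient design)"
            )


def _fit_mixed(
    formula: str,
    t: pd.DataFrame,
    vc: dict[str, str],
    vc_names: tuple[str, str],
) -> LMMResult:
    warns: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(
            formula, data=t, groups=np.ones(len(t)), vc_formula=vc
        )
        try:
            res = model.fit(reml=True, method="lbfgs")
        except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
            raise InferenceError(f"mixed-model fit failed: {exc}") from exc
        warns = [str(w.message) for w in caught]
    converged = bool(getattr(res, "converged", True))
    fe_names = [n for n in res.fe_params.index]
    est = res.fe_params.to_numpy()
    se = res.bse_fe.to_numpy()
    zcrit = stats.norm.ppf(0.975)
    pvals = 2 * stats.norm.sf(np.abs(est / se))
    vcomp = dict(zip(model.exog_vc.names, np.atleast_1d(res.vcomp)))
    return LMMResult(
        names=tuple(fe_names),
        estimates=est,
        std_errors=se,
        ci_low=est - zcrit * se,
        ci_high=est + zcrit * se,
        p_values=pvals,
        vc_scorer=float(vcomp.get(vc_names[0], np.nan)),
        vc_seizure=float(vcomp.get(vc_names[1], np.nan)),
        resid_var=float(res.scale),
        converged=converged,
        warnings_=tuple(warns),
    )


_VC_SCORER_SEIZURE = {
    "scorer": "0 + C(scorer_id)",
    "seizure": "0 + C(seizure_id)",
}


def fit_area_model(t: pd.DataFrame, extra_fixed: list[str] | None = None) -> LMMResult:
    """Log annotated area on density, multifocality, clinical overlap and
    confidence; crossed random intercepts for scorer and seizure."""
    t = validate_score_table(t)
    if t["scorer_id"].nunique() < 2 or t["seizure_id"].nunique() < 2:
        raise InferenceError("need >= 2 scorers and >= 2 seizures")
    terms = ["density", "multifocal", "overlaps_clinical", "confidence"]
    terms += extra_fixed or []
    _check_not_constant(t, ["density"] + (extra_fixed or []))
    t = t.assign(
        multifocal=t["multifocal"].astype(int),
        overlaps_clinical=t["overlaps_clinical"].astype(int),
        confidence=t["confidence"].astype(float),
    )
    return _fit_mixed(
        "log_area ~ " + " + ".join(terms), t, _VC_SCORER_SEIZURE,
        ("scorer", "seizure"),
    )


def fit_confidence_model(
    t: pd.DataFrame, extra_fixed: list[str] | None = None
) -> LMMResult:
    """Likert confidence (treated numeric) on density, multifocality,
    clinical overlap and the scorer's mean pairwise kappa."""
    t = validate_score_table(t)
    if t["confidence"].nunique() < 2:
        # constant outcome: residual variance 0, nothing to estimate
        k = 5
        zeros = np.zeros(k)
        return LMMResult(
            names=("Intercept", "density", "multifocal", "overlaps_clinical",
                   "scorer_mean_kappa"),
            estimates=np.array([float(t["confidence"].iloc[0]), 0, 0, 0, 0]),
            std_errors=zeros, ci_low=zeros, ci_high=zeros,
            p_values=np.full(k, np.nan),
            vc_scorer=0.0, vc_seizure=0.0, resid_var=0.0,
            converged=False, warnings_=("constant outcome: degenerate fit",),
        )
    terms = ["density", "multifocal", "overlaps_clinical", "scorer_mean_kappa"]
    terms += extra_fixed or []
    _check_not_constant(t, ["density"] + (extra_fixed or []))
    t = t.assign(
        multifocal=t["multifocal"].astype(int),
        overlaps_clinical=t["overlaps_clinical"].astype(int),
        confidence=t["confidence"].astype(float),
    )
    return _fit_mixed(
        "confidence ~ " + " + ".join(terms), t, _VC_SCORER_SEIZURE,
        ("scorer", "seizure"),
    )


def fit_kappa_model(k: pd.DataFrame) -> LMMResult:
    """Pairwise kappa on density with random intercepts for scorer pair and
    seizure.

    ``k`` is long format with columns pair_id (or scorer_a/scorer_b),
    seizure_id, condition, kappa. With a single seizure and a single pair
    the mixed model is unidentifiable; the fit falls back to a paired
    t-test on the HD - LD difference with a warning.
    """
    k = k.copy()
    if "pair_id" not in k.columns:
        if {"scorer_a", "scorer_b"} <= set(k.columns):
            k["pair_id"] = k["scorer_a"].astype(str) + "|" + k["scorer_b"].astype(str)
        else:
            raise InferenceError("kappa table needs pair_id or scorer_a/scorer_b")
    k = k.dropna(subset=["kappa"])
    k["density"] = (k["condition"].astype(str) == "HD").astype(int)
    _check_not_constant(k, ["density"])
    if k["pair_id"].nunique() < 2 and k["seizure_id"].nunique() < 2:
        warnings.warn(
            "single pair and seizure: falling back to a paired difference",
            stacklevel=2,
        )
        piv = k.pivot_table(index=["pair_id", "seizure_id"], columns="condition",
                            values="kappa")
        diff = (piv["HD"] - piv["LD"]).dropna().to_numpy()
        est = float(diff.mean())
        se = float(diff.std(ddof=1) / np.sqrt(len(diff))) if len(diff) > 1 else np.nan
        z = stats.norm.ppf(0.975)
        p = 2 * stats.norm.sf(abs(est / se)) if np.isfinite(se) and se > 0 else np.nan
        return LMMResult(
            names=("density",), estimates=np.array([est]),
            std_errors=np.array([se]),
            ci_low=np.array([est - z * se]), ci_high=np.array([est + z * se]),
            p_values=np.array([p]), vc_scorer=np.nan, vc_seizure=np.nan,
            resid_var=np.nan, converged=True, method="paired-difference",
            warnings_=("degenerate design: paired difference",),
        )
    vc = {"pair": "0 + C(pair_id)", "seizure": "0 + C(seizure_id)"}
    return _fit_mixed("kappa ~ density", k, vc, ("pair", "seizure"))


def add_carryover(model: str, t: pd.DataFrame) -> LMMResult:
    """Refit the area or confidence model with the first-shown condition
    (HD-first vs LD-first) as an extra fixed effect and report its p-value."""
    if "order_first" not in t.columns:
        raise InferenceError("score table has no order_first column")
    if model == "area":
        return fit_area_model(t, extra_fixed=["hd_first"])
    if model == "confidence":
        return fit_confidence_model(t, extra_fixed=["hd_first"])
    raise InferenceError(f"unknown model {model!r}; use 'area' or 'confidence'")


def percent_change_from_log_coef(beta: float) -> float:
    """Percent change implied by a coefficient on a natural-log outcome."""
    return 100.0 * (np.exp(beta) - 1.0)


def effective_sample_size(n: int, deff: float) -> float:
    """Clustering-adjusted effective sample size ``n / DEFF``."""
    if deff <= 0:
        raise InferenceError("design effect must be positive")
    return n / deff


def min_detectable_effect(
    n_per_arm: int,
    power: float = 0.80,
    alpha: float = 0.05,
    two_sided: bool = True,
) -> float:
    """Minimum detectable standardised difference for a two-sample t-test
    (noncentral-t power equation), monotone decreasing in n."""
    if not 0 < power < 1:
        raise InferenceError("power must be in (0, 1)")
    if n_per_arm < 2:
        raise InferenceError("need n >= 2 per arm")
    alternative = "two-sided" if two_sided else "larger"
    d = TTestIndPower().solve_power(
        effect_size=None, nobs1=n_per_arm, ratio=1.0, alpha=alpha,
        power=power, alternative=alternative,
    )
    return float(np.atleast_1d(d)[0])
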