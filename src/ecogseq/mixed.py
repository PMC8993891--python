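"""Thin wrappers around statsmodels mixed-effects machinery.

Linear mixed models (REML) come from :class:`statsmodels MixedLM`; logistic
mixed models from :class:`BinomialBayesMixedGLM` (MAP with Laplace
observed-information SEs, variational Bayes as a secondary route), with a
fixed-effects GLM fallback (group dummies) and an L2-penalized logistic
fallback under complete separation. Satterthwaite degrees of freedom are not
available in statsmodels, so p-values use the normal approximation with the
residual df reported; the method string on each estimate records which route
produced it, including fit-health fallbacks (simplified random structure on
convergence failure or a non-positive-definite covariance).
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .io import EffectEstimate

__all__ = ["fit_lmm", "fit_logistic_mixed"]


def _estimate(name, b, se, n, k, method, logistic=False) -> EffectEstimate:
    se = float(max(se, 1e-12))
    df = float(max(n - k, 1))
    z = b / se
    p = float(min(2.0 * sps.norm.sf(abs(z)), 1.0))
    if logistic:
        return EffectEstimate.logistic(name, float(b), se, p, df, method=method)
    return EffectEstimate(name=name, b=float(b), se=se, p=p, df=df, method=method)


def _ols(data, formula, effects, method) -> dict:
    fit = smf.ols(formula, data=data).fit()
    out = {}
    for term, name in effects.items():
        out[name] = _estimate(
            name, fit.params[term], fit.bse[term], len(data), len(fit.params), method
        )
    return out


def fit_lmm(
    data: pd.DataFrame,
    formula: str,
    effects: dict,
    groups: Optional[str] = None,
    re_formula: Optional[str] = None,
    vc_formula: Optional[dict] = None,
) -> dict:
    """Fit a linear mixed model, returning {effect name: EffectEstimate}.

    ``effects`` maps design-matrix term names to output effect names. Falls
    back along: full random structure -> independent random intercept -> OLS,
    recording the route in each estimate's ``method``. A single grouping level
    goes straight to OLS (no between-group variance to estimate).
    """
    data = data.reset_index(drop=True)
    if groups is None or data[groups].nunique() < 2:
        return _ols(data, formula, effects, "ols")

    # Reference fit for the boundary-degeneracy health check below.
    ols_fit = smf.ols(formula, data=data).fit()

    attempts = [
        ("lmm", dict(re_formula=re_formula, vc_formula=vc_formula)),
        ("lmm-simplified", dict(re_formula=None, vc_formula=None)),
    ]
    for method, kw in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data=data, groups=data[groups], **{
                    k: v for k, v in kw.items() if v is not None
                })
                fit = model.fit(reml=True, maxiter=200)
            if not np.all(np.isfinite([fit.params.get(t, np.nan) for t in effects])):
                continue
            if not np.all(np.isfinite([fit.bse.get(t, np.nan) for t in effects])):
                continue
            # Fit-health check: a boundary/degenerate solution can park fixed
            # effects far from any plausible value; reject fits whose effects
            # sit implausibly far from the pooled OLS estimate.
            bad = False
            for term in effects:
                gap = abs(fit.params[term] - ols_fit.params[term])
                ols_se = max(ols_fit.bse[term], 1e-12)
                if gap > 10.0 * ols_se or fit.bse[term] > 50.0 * ols_se:
                    bad = True
                    break
            if bad:
                continue
            out = {}
            for term, name in effects.items():
                out[name] = _estimate(
                    name, fit.params[term], fit.bse[term], len(data),
                    len(fit.fe_params), method,
                )
            return out
        except Exception:
            continue
    return _ols(data, formula, effects, "ols-fallback")


def _penalized_logit(y, X, names, effects) -> dict:
    """Ridge-penalized logistic fit for separated data; SEs from the penalized
    information matrix. Flagged via method='logit-penalized-separation'."""
    alpha = 1.0
    model = sm.GLM(y, X, family=sm.families.Binomial())
    fit = model.fit_regularized(alpha=alpha, L1_wt=0.0)
    beta = np.asarray(fit.params, dtype=float)
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1 - mu)
    H = X.T @ (X * W[:, None]) + 2 * alpha * np.eye(X.shape[1])
    cov = np.linalg.inv(H)
    out = {}
    for term, name in effects.items():
        j = names.index(term)
        out[name] = _estimate(
            name, beta[j], np.sqrt(cov[j, j]), len(y), X.shape[1],
            "logit-penalized-separation", logistic=True,
        )
    return out


def fit_logistic_mixed(
    data: pd.DataFrame,
    formula: str,
    effects: dict,
    vc_groups: Sequence[str] = (),
) -> dict:
    """Logistic mixed-effects classification.

    Primary route: binomial mixed GLM (MAP + Laplace) with one variance
    component per grouping factor in ``vc_groups``; VB if MAP fails.
    Fallbacks: plain GLM with group dummies for the first factor, then a
    penalized logit under complete separation. Odds ratios (exp(b))
    accompany every effect.
    """
    data = data.reset_index(drop=True)
    vc = {g: f"0 + C({g})" for g in vc_groups if data[g].nunique() > 1}
    if vc:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

                model = BinomialBayesMixedGLM.from_formula(formula, vc, data)
                # MAP + Laplace gives observed-information SEs (mean-field VB
                # understates them); the VB fallback Monte-Carlo integrates
                # the ELBO through the global RandomState, so pin it
                state = np.random.get_state()
                np.random.seed(1234)
                try:
                    try:
                        fit = model.fit_map()
                        method_name = "logistic-mixed-map"
                    except Exception:
                        fit = model.fit_vb()
                        method_name = "logistic-mixed-vb"
                finally:
                    np.random.set_state(state)
            names = list(model.exog_names)
            out = {}
            ok = True
            for term, name in effects.items():
                j = names.index(term)
                b = fit.fe_mean[j]
                se = fit.fe_sd[j]
                if not (np.isfinite(b) and np.isfinite(se) and se > 1e-8):
                    ok = False
                    break
                out[name] = _estimate(
                    name, b, se, len(data), len(names), method_name,
                    logistic=True,
                )
            if ok:
                return out
        except Exception:
            pass

    # fixed-effects fallback: dummies for the first grouping factor
    import patsy

    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    if vc_groups and data[vc_groups[0]].nunique() > 1:
        dummies = pd.get_dummies(
            data[vc_groups[0]], prefix="g", drop_first=True, dtype=float
        )
        X = pd.concat([X, dummies], axis=1)
    names = list(X.columns)
    Xm = X.to_numpy(float)
    ym = np.asarray(y).ravel()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(ym, Xm, family=sm.families.Binomial()).fit()
        if not np.all(np.isfinite(fit.bse)) or np.any(fit.bse > 1e3):
            raise ValueError("separation suspected")
        out = {}
        for term, name in effects.items():
            j = names.index(term)
            out[name] = _estimate(
                name, fit.params[j], fit.bse[j], len(ym), Xm.shape[1],
                "logistic-glm", logistic=True,
            )
        return out
    except Exception:
        return _penalized_logit(ym, Xm, names, effects)
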