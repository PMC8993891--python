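"""Aggregate ROI mixed-model analyses of single-trial activation metrics.

Covers the robust multi-site outlier rules (3 scaled-MAD residual flagging per
site, then per ROI, with whole-site exclusion above 50% flagged observations),
the per-ROI models of mentalizing type / RT / choice effects on each metric,
RT-controlled pairwise ROI latency contrasts, the logistic classification of
mentalizing-specificity from onset latency, second-level onset-vs-effect-size
models, and the post-hoc contrast of how closely activation offsets precede
the behavioral response in mPFC versus other ROIs.

Codings follow the printed-difference convention: mentalizing type is
+1/2 (other) / -1/2 (self) so a positive Type effect reads other-minus-self,
and choice is +1/2 (true) / -1/2 (false).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .io import EffectEstimate, MPFC_ROIS
from .mixed import fit_lmm, fit_logistic_mixed
from .stats import bisquare_regress, fdr_by, mad_scaled

__all__ = [
    "METRIC_COLUMNS",
    "RoiModelResult",
    "multisite_outlier_filter",
    "fit_roi_type_rt_choice",
    "pairwise_roi_latency",
    "pairwise_roi_matrix",
    "site_rt_effects",
    "onset_predicts_specificity",
    "onset_vs_effect_size",
    "mpfc_offset_vs_rt",
    "roi_model_table",
]

METRIC_COLUMNS = ("onset_ms", "peak_ms", "offset_ms", "duration_ms", "peak_power_z")
RT_MAX_MS = 5000.0
MIN_SITE_OBS = 8


@dataclass
class RoiModelResult:
    roi: str
    metric: str
    effects: dict = field(default_factory=dict)  # name -> EffectEstimate
    n_obs: int = 0


def _mentalizing_rows(metrics: pd.DataFrame) -> pd.DataFrame:
    out = metrics[metrics["condition"].isin(["self", "other"])].copy()
    out = out[np.isfinite(out["rt_ms"]) & (out["rt_ms"] <= RT_MAX_MS)]
    return out


def _flag_outliers(values: np.ndarray, rt: np.ndarray, threshold: float,
                   method: str) -> np.ndarray:
    """Residual-based robust outlier flags for one metric against RT."""
    ok = np.isfinite(values) & np.isfinite(rt)
    flags = np.zeros(values.size, dtype=bool)
    if ok.sum() < MIN_SITE_OBS:
        return flags
    if method == "mahalanobis":
        # Bivariate alternative: robust z on [value, rt] via coordinatewise
        # median/MAD, flag on the euclidean norm.
        v = values[ok]
        r = rt[ok]
        mads = np.array([max(mad_scaled(v), 1e-12), max(mad_scaled(r), 1e-12)])
        z = np.column_stack([(v - np.median(v)) / mads[0], (r - np.median(r)) / mads[1]])
        d = np.sqrt((z**2).sum(axis=1))
        flags[ok] = d > threshold
        return flags
    if np.ptp(rt[ok]) < 1e-9:  # constant RT: intercept-only residuals
        X = np.ones((ok.sum(), 1))
    else:
        X = np.column_stack([np.ones(ok.sum()), rt[ok]])
    fit = bisquare_regress(X, values[ok])
    scale = mad_scaled(fit.residuals)
    if scale > 0:
        flags[ok] = np.abs(fit.residuals) > threshold * scale
    return flags


def multisite_outlier_filter(
    metrics: pd.DataFrame,
    active_sites: Sequence[str],
    threshold: float = 3.0,
    site_exclude_frac: float = 0.5,
    method: str = "regression",
):
    """Two-stage robust outlier filtering of mentalizing-trial metrics.

    Stage 1 flags, per site and metric, observations whose bisquare-regression
    residual against RT exceeds ``threshold`` scaled MADs. Stage 2 repeats the
    rule pooling all mentalizing-active sites of each ROI, and removes sites
    with more than ``site_exclude_frac`` of their observations flagged.
    Trials with RT over 5000 ms are excluded first. Flagged observations are
    set to NaN in the returned copy. Returns
    ``(filtered_metrics, excluded_sites, flag_summary)``.
    """
    if metrics.empty:
        return metrics.copy(), [], pd.DataFrame(
            columns=["site_id", "n_obs", "n_flagged", "frac"]
        )
    df = _mentalizing_rows(metrics)
    df = df[df["site_id"].isin(active_sites) & (df["roi"] != "none")].copy()
    if df.empty:
        return df, [], pd.DataFrame(columns=["site_id", "n_obs", "n_flagged", "frac"])

    rt = df["rt_ms"].to_numpy(float)
    flagged = {m: np.zeros(len(df), dtype=bool) for m in METRIC_COLUMNS}
    for sid, idx in df.groupby("site_id").indices.items():
        for m in METRIC_COLUMNS:
            vals = df[m].to_numpy(float)[idx]
            if np.isfinite(vals).sum() < MIN_SITE_OBS:
                continue  # too few observations: passes through unfiltered
            flagged[m][idx] |= _flag_outliers(vals, rt[idx], threshold, method)

    stage2 = {m: np.zeros(len(df), dtype=bool) for m in METRIC_COLUMNS}
    for roi, idx in df.groupby("roi").indices.items():
        for m in METRIC_COLUMNS:
            vals = df[m].to_numpy(float)[idx]
            vals = np.where(flagged[m][idx], np.nan, vals)
            stage2[m][idx] |= _flag_outliers(vals, rt[idx], threshold, method)

    total_flags = np.zeros(len(df), dtype=int)
    total_obs = np.zeros(len(df), dtype=int)
    out = df.copy()
    for m in METRIC_COLUMNS:
        f = flagged[m] | stage2[m]
        obs = np.isfinite(df[m].to_numpy(float))
        total_flags += (f & obs).astype(int)
        total_obs += obs.astype(int)
        out.loc[f, m] = np.nan

    summary = (
        pd.DataFrame(
            {"site_id": df["site_id"].to_numpy(), "n_obs": total_obs, "n_flagged": total_flags}
        )
        .groupby("site_id", as_index=False)
        .sum()
    )
    summary["frac"] = summary["n_flagged"] / summary["n_obs"].clip(lower=1)
    excluded = summary.loc[summary["frac"] > site_exclude_frac, "site_id"].tolist()
    out = out[~out["site_id"].isin(excluded)].reset_index(drop=True)
    return out, excluded, summary


def fit_roi_type_rt_choice(
    metrics: pd.DataFrame, roi: str, metric: str
) -> Optional[RoiModelResult]:
    """Per-ROI LMEMs of one activation metric (mentalizing trials).

    Two companion models sharing site/participant nesting: (i) a mentalizing
    type model (Type other-minus-self, controlling RT and visual-dissimilarity
    covariates) and (ii) a behavior model (RT and Choice jointly, controlling
    VDs). Random structure: participant grouping with a site variance
    component, simplified on fit failure.
    """
    df = _mentalizing_rows(metrics)
    df = df[(df["roi"] == roi) & np.isfinite(df[metric])].copy()
    df = df[df["choice"].isin(["true", "false"])]
    if len(df) < 12 or df["site_id"].nunique() < 1:
        return None
    df["value"] = df[metric].astype(float)
    df["type_c"] = np.where(df["condition"] == "other", 0.5, -0.5)
    df["choice_c"] = np.where(df["choice"] == "true", 0.5, -0.5)

    multi_site = df["site_id"].nunique() > 1
    vc = {"site": "0 + C(site_id)"} if multi_site else None
    eff = {}
    eff.update(
        fit_lmm(
            df, "value ~ type_c + rt_ms + vd1 + vd2",
            {"type_c": "Type_Other-Self"},
            groups="participant_id", re_formula="1", vc_formula=vc,
        )
    )
    eff.update(
        fit_lmm(
            df, "value ~ rt_ms + choice_c + vd1 + vd2",
            {"rt_ms": "RT_Behav", "choice_c": "Choice_True-False",
             "vd1": "VD1", "vd2": "VD2"},
            groups="participant_id", re_formula="1", vc_formula=vc,
        )
    )
    return RoiModelResult(roi=roi, metric=metric, effects=eff, n_obs=len(df))


def roi_model_table(metrics: pd.DataFrame, rois: Sequence[str]) -> pd.DataFrame:
    """Tidy table of Type/RT/Choice effects per ROI x metric."""
    rows = []
    for roi in rois:
        for metric in METRIC_COLUMNS:
            res = fit_roi_type_rt_choice(metrics, roi, metric)
            if res is None:
                continue
            for name, est in res.effects.items():
                rows.append(
                    {"roi": roi, "metric": metric, "effect": name,
                     "b": est.b, "se": est.se, "p": est.p, "df": est.df,
                     "n_obs": res.n_obs, "method": est.method}
                )
    return pd.DataFrame(rows)


def pairwise_roi_latency(
    metrics: pd.DataFrame, roi_x: str, roi_y: str, metric: str = "onset_ms"
) -> Optional[EffectEstimate]:
    """Within-trial ROI_X - ROI_Y latency contrast, RT-controlled.

    Restricted to participants with mentalizing-active sites in both ROIs;
    each trial contributes the difference of its per-ROI site means, modeled
    with a participant random intercept and a centered-RT covariate. Returns
    None when no participant samples both ROIs. Exactly antisymmetric in
    (roi_x, roi_y).
    """
    if roi_x == roi_y:
        return EffectEstimate(name=f"{roi_x}-{roi_y}", b=0.0, se=1e-12, p=1.0, df=1.0)
    df = _mentalizing_rows(metrics)
    df = df[np.isfinite(df[metric])]
    hx = df[df["roi"] == roi_x]
    hy = df[df["roi"] == roi_y]
    shared = sorted(set(hx["participant_id"]) & set(hy["participant_id"]))
    if not shared:
        return None
    gx = hx.groupby(["participant_id", "trial_id"])[metric].mean()
    gy = hy.groupby(["participant_id", "trial_id"])[metric].mean()
    rt = df.groupby(["participant_id", "trial_id"])["rt_ms"].first()
    pair = pd.DataFrame({"x": gx, "y": gy, "rt_ms": rt}).dropna().reset_index()
    pair = pair[pair["participant_id"].isin(shared)]
    if len(pair) < 5:
        return None
    pair["d"] = pair["x"] - pair["y"]
    pair["rt_c"] = pair["rt_ms"] - pair["rt_ms"].mean()
    eff = fit_lmm(
        pair, "d ~ rt_c", {"Intercept": f"{roi_x}-{roi_y}"},
        groups="participant_id", re_formula="1",
    )
    return eff[f"{roi_x}-{roi_y}"]


def pairwise_roi_matrix(
    metrics: pd.DataFrame, rois: Sequence[str], metric: str = "onset_ms",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All unique ROI-pair contrasts for one metric, BY-corrected per metric."""
    rows = []
    for rx, ry in combinations(rois, 2):
        est = pairwise_roi_latency(metrics, rx, ry, metric)
        if est is None:
            rows.append({"roi_x": rx, "roi_y": ry, "metric": metric, "b": np.nan,
                         "se": np.nan, "p": np.nan, "estimable": False})
        else:
            rows.append({"roi_x": rx, "roi_y": ry, "metric": metric, "b": est.b,
                         "se": est.se, "p": est.p, "estimable": True})
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    df["sig"] = False
    ok = df["estimable"] & np.isfinite(df["p"])
    if ok.any():
        adj = fdr_by(df.loc[ok, "p"].to_numpy())
        df.loc[ok, "p_adj"] = adj
        df.loc[ok, "sig"] = adj < alpha
    return df


def site_rt_effects(
    metrics: pd.DataFrame, metric: str = "peak_ms"
) -> pd.DataFrame:
    """Per-site RT slope for one metric (site-level effect sizes).

    Primary route: best linear unbiased predictions from a MixedLM with a
    random RT slope per site; falls back to independent per-site OLS slopes
    when the random-slope fit fails (method column records the route).
    """
    df = _mentalizing_rows(metrics)
    df = df[np.isfinite(df[metric]) & df["choice"].isin(["true", "false"])].copy()
    df["value"] = df[metric].astype(float)
    df["choice_c"] = np.where(df["choice"] == "true", 0.5, -0.5)
    meta = df.groupby("site_id").agg(
        participant_id=("participant_id", "first"), roi=("roi", "first"),
        mean_onset_ms=("onset_ms", "mean"), n=("value", "size"),
    )

    slopes = None
    method = "blup"
    if df["site_id"].nunique() > 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    "value ~ rt_ms + choice_c + vd1 + vd2", data=df,
                    groups=df["site_id"], re_formula="~rt_ms",
                )
                fit = model.fit(reml=True, maxiter=200)
            fe = fit.fe_params["rt_ms"]
            re = fit.random_effects
            slopes = {sid: fe + re[sid].get("rt_ms", 0.0) for sid in re}
            if not all(np.isfinite(list(slopes.values()))):
                slopes = None
        except Exception:
            slopes = None
    if slopes is None:
        method = "per-site-ols"
        slopes = {}
        for sid, sub in df.groupby("site_id"):
            if len(sub) < MIN_SITE_OBS:
                continue
            try:
                fit = smf.ols("value ~ rt_ms + choice_c + vd1 + vd2", data=sub).fit()
                slopes[sid] = float(fit.params["rt_ms"])
            except Exception:
                continue
    out = meta.loc[meta.index.isin(slopes)].copy()
    out["rt_slope"] = [slopes[s] for s in out.index]
    out["method"] = method
    return out.reset_index()


def onset_predicts_specificity(site_table: pd.DataFrame) -> EffectEstimate:
    """Log-odds of mentalizing-specificity per ms of mean onset latency.

    ``site_table`` needs participant_id, mean_onset_ms and a boolean
    ``specific`` column (one row per mentalizing-active ROI site); the model
    is a participant-nested logistic mixed classification.
    """
    df = site_table.dropna(subset=["mean_onset_ms"]).copy()
    if df["specific"].nunique() < 2:
        # complete separation by construction; penalized path handles it
        pass
    elif min((df["specific"]).sum(), (~df["specific"]).sum()) < 2:
        warnings.warn("fewer than 2 sites in one specificity class", stacklevel=2)
    df["y"] = df["specific"].astype(int)
    # Fit on a rescaled covariate (100-ms units) so the logistic optimizer is
    # well conditioned, then report the slope per millisecond.
    scale = 100.0
    df["onset_x"] = (df["mean_onset_ms"] - df["mean_onset_ms"].mean()) / scale
    eff = fit_logistic_mixed(
        df, "y ~ onset_x", {"onset_x": "onset_to_specificity"},
        vc_groups=["participant_id"],
    )
    e = eff["onset_to_specificity"]
    return EffectEstimate.logistic(
        e.name, e.b / scale, e.se / scale, e.p, e.df, method=e.method
    )


def onset_vs_effect_size(site_table: pd.DataFrame, effect_col: str = "rt_slope") -> EffectEstimate:
    """Second-level slope of per-site effect sizes on mean onset latency."""
    df = site_table.dropna(subset=["mean_onset_ms", effect_col]).copy()
    if len(df) < 10:
        raise ValueError("need at least 10 sites for the second-level model")
    df["effect"] = df[effect_col].astype(float)
    eff = fit_lmm(
        df, "effect ~ mean_onset_ms", {"mean_onset_ms": "onset_to_effect"},
        groups="participant_id", re_formula="1",
    )
    return eff["onset_to_effect"]


def mpfc_offset_vs_rt(metrics: pd.DataFrame) -> EffectEstimate:
    """How closely activation offsets precede the behavioral response, mPFC vs rest.

    Models rt - offset with a +1/2 (non-mPFC) / -1/2 (mPFC) indicator under
    participant nesting: a positive slope means non-mPFC offsets precede the
    response by more (mPFC activity runs closer to the response).
    """
    df = _mentalizing_rows(metrics)
    df = df[np.isfinite(df["offset_ms"]) & (df["roi"] != "none")].copy()
    if not df["roi"].isin(MPFC_ROIS).any():
        raise ValueError("no mPFC sites with activation offsets")
    df["gap"] = df["rt_ms"] - df["offset_ms"]
    df["mpfc_c"] = np.where(df["roi"].isin(MPFC_ROIS), -0.5, 0.5)
    eff = fit_lmm(
        df, "gap ~ mpfc_c", {"mpfc_c": "nonmPFC-mPFC_offset_gap"},
        groups="participant_id", re_formula="1",
    )
    return eff["nonmPFC-mPFC_offset_gap"]
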