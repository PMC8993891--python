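"""Trial-averaged evoked-timecourse estimation and site response labeling.

Per-site, per-condition mean timecourses of evoked HFB power (beta) relative
to the pre-stimulus baseline. Because epochs are baseline-corrected per trial,
the mixed model with one dummy per peri-stimulus timepoint and a per-trial
random intercept reduces algebraically to the paired contrast between each
timepoint and the trial's baseline mean: beta(t) is the cross-trial mean of
the corrected trace, its SE the cross-trial standard error, and the p-value a
paired t-test. P-values are BY-adjusted across timepoints and sites, the 50-ms
persistence rule applies, and sites are labeled active / deactive /
nonresponsive (mixed polarity resolved by the greatest deflection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import HFBEpochs
from .single_trial import enforce_min_run, joint_fdr

__all__ = [
    "TimecourseEstimate",
    "fit_site_timecourse",
    "label_response",
    "run_trial_averaged",
    "time_window_summary",
    "grand_average_roi",
    "DEFAULT_WINDOWS_MS",
]

DEFAULT_WINDOWS_MS = ((0, 250), (250, 500), (500, 750), (750, 1000), (1000, 2000))
MIN_TRIALS = 8


@dataclass
class TimecourseEstimate:
    """Evoked HFB beta(t) with SE, adjusted p and persistence-filtered mask."""

    site_id: str
    condition: str
    time_axis: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray  # raw paired-t p; adjusted copy filled by run_trial_averaged
    p_adj: Optional[np.ndarray] = None
    sig: Optional[np.ndarray] = None
    n_trials: int = 0
    roi: str = "none"
    participant_id: str = ""


def _condition_trials(epochs: HFBEpochs, condition) -> np.ndarray:
    if condition == "mentalizing":
        return epochs.condition_mask(["self", "other"])
    return epochs.condition_mask(condition)


def fit_site_timecourse(
    epochs: HFBEpochs, site_id: str, condition: str, min_trials: int = MIN_TRIALS
) -> Optional[TimecourseEstimate]:
    """Per-timepoint evoked effect for one site and condition.

    ``condition`` may be a task condition or ``"mentalizing"`` (self + other
    collapsed). Returns None (with a warning) when fewer than ``min_trials``
    trials survive exclusions.
    """
    s = epochs.site_index(site_id)
    tsel = _condition_trials(epochs, condition)
    if tsel.sum() < min_trials:
        warnings.warn(
            f"site {site_id} condition {condition}: only {int(tsel.sum())} trials; skipped",
            stacklevel=2,
        )
        return None
    data = np.where(epochs.valid_mask[s, tsel], epochs.hfb[s, tsel].astype(float), np.nan)
    post = epochs.time_axis >= 0
    data = data[:, post]
    n = np.sum(np.isfinite(data), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        beta = np.nanmean(data, axis=0)
        sd = np.nanstd(data, axis=0, ddof=1)
    ok = n >= min_trials
    se = np.where(ok & (sd > 0), sd / np.sqrt(np.maximum(n, 1)), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
    p = np.full(beta.shape, np.nan)
    fin = np.isfinite(tstat)
    p[fin] = 2.0 * sps.t.sf(np.abs(tstat[fin]), n[fin] - 1)
    beta = np.where(ok, beta, np.nan)
    info = epochs.sites[s]
    return TimecourseEstimate(
        site_id=site_id,
        condition=condition,
        time_axis=epochs.time_axis[post],
        beta=beta,
        se=se,
        p=np.minimum(p, 1.0),
        n_trials=int(tsel.sum()),
        roi=info.roi,
        participant_id=info.participant_id,
    )


def label_response(estimate: Optional[TimecourseEstimate]) -> str:
    """'active' / 'deactive' / 'nonresponsive' from the significance pattern.

    Active if only positive significant timepoints, deactive if only negative;
    mixed patterns take the polarity of the greatest absolute deflection among
    significant timepoints.
    """
    if estimate is None or estimate.sig is None or not estimate.sig.any():
        return "nonresponsive"
    sig_beta = estimate.beta[estimate.sig]
    pos = (sig_beta > 0).any()
    neg = (sig_beta < 0).any()
    if pos and not neg:
        return "active"
    if neg and not pos:
        return "deactive"
    return "active" if sig_beta[np.argmax(np.abs(sig_beta))] > 0 else "deactive"


def run_trial_averaged(
    epochs: HFBEpochs,
    conditions: Sequence[str] = ("self", "other", "cognitive", "mentalizing"),
    alpha: float = 0.05,
    min_run_ms: float = 50.0,
) -> tuple[dict, pd.DataFrame]:
    """Fit every site x condition timecourse and label responses.

    BY correction pools timepoints across sites (one family per condition).
    Returns ``(estimates, labels)`` where estimates maps
    (site_id, condition) -> TimecourseEstimate and labels is a tidy table.
    """
    estimates: dict = {}
    label_rows = []
    for cond in conditions:
        fits = []
        for c in epochs.sites:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = fit_site_timecourse(epochs, c.site_id, cond)
            if est is not None:
                fits.append(est)
        if fits:
            pooled = np.stack([f.p for f in fits])
            adj, sig = joint_fdr(pooled, alpha)
            for i, f in enumerate(fits):
                f.p_adj = adj[i]
                f.sig = enforce_min_run(
                    np.where(np.isfinite(adj[i]), sig[i], False),
                    min_run_ms,
                    epochs.step_ms,
                )
        for f in fits:
            estimates[(f.site_id, cond)] = f
            label_rows.append(
                {
                    "participant_id": f.participant_id,
                    "site_id": f.site_id,
                    "roi": f.roi,
                    "condition": cond,
                    "label": label_response(f),
                    "n_trials": f.n_trials,
                }
            )
    return estimates, pd.DataFrame(label_rows)


def time_window_summary(
    epochs: HFBEpochs,
    windows: Sequence[tuple] = DEFAULT_WINDOWS_MS,
    conditions: Sequence[str] = ("self", "other", "cognitive"),
    alpha: float = 0.05,
    min_trials: int = MIN_TRIALS,
) -> pd.DataFrame:
    """Signed t of evoked HFB power per site x condition x time window.

    Each trial contributes its mean corrected HFB over the window's valid
    timepoints (a paired comparison against that trial's baseline); windows
    are half-open [a, b) ms. BY correction runs across sites x windows per
    condition. Windows with no valid samples are flagged untested.
    """
    for a, b in windows:
        if b > epochs.time_axis[-1] + epochs.step_ms:
            raise ValueError(f"window [{a}, {b}) exceeds the epoch range")
    rows = []
    for cond in conditions:
        tsel = _condition_trials(epochs, cond)
        for s, site in enumerate(epochs.sites):
            data = np.where(
                epochs.valid_mask[s, tsel], epochs.hfb[s, tsel].astype(float), np.nan
            )
            for a, b in windows:
                wsel = (epochs.time_axis >= a) & (epochs.time_axis < b)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    per_trial = np.nanmean(data[:, wsel], axis=1)
                per_trial = per_trial[np.isfinite(per_trial)]
                if per_trial.size < min_trials or per_trial.std(ddof=1) == 0:
                    rows.append(
                        dict(site_id=site.site_id, roi=site.roi, condition=cond,
                             window_start_ms=a, window_end_ms=b, t=np.nan,
                             p=np.nan, n=per_trial.size, tested=False)
                    )
                    continue
                t = per_trial.mean() / (per_trial.std(ddof=1) / np.sqrt(per_trial.size))
                p = 2.0 * sps.t.sf(abs(t), per_trial.size - 1)
                rows.append(
                    dict(site_id=site.site_id, roi=site.roi, condition=cond,
                         window_start_ms=a, window_end_ms=b, t=float(t),
                         p=float(min(p, 1.0)), n=per_trial.size, tested=True)
                )
    df = pd.DataFrame(rows)
    df["p_adj"] = np.nan
    df["sig"] = False
    for cond in conditions:
        fam = df["condition"].eq(cond) & df["tested"]
        if fam.any():
            adj = np.full(fam.sum(), np.nan)
            from .stats import fdr_by

            adj = fdr_by(df.loc[fam, "p"].to_numpy())
            df.loc[fam, "p_adj"] = adj
            df.loc[fam, "sig"] = adj < alpha
    return df


def grand_average_roi(
    site_estimates: Sequence[TimecourseEstimate],
    roi: str,
    condition: str,
    max_ms: float = 3000.0,
) -> Optional[TimecourseEstimate]:
    """Pooled ROI timecourse over [0, max_ms] from responsive sites.

    Two-stage aggregation: per-site paired estimates (trial level) are averaged
    across sites, with the SE taken across sites when more than one contributes
    (approximating site/participant random effects) and passed through from
    the single site otherwise.
    """
    fits = [f for f in site_estimates if f.roi == roi and f.condition == condition]
    if not fits:
        return None
    tsel = fits[0].time_axis <= max_ms
    time_axis = fits[0].time_axis[tsel]
    B = np.stack([f.beta[tsel] for f in fits])
    if len(fits) == 1:
        f = fits[0]
        return TimecourseEstimate(
            site_id=f"roi:{roi}", condition=condition, time_axis=time_axis,
            beta=B[0], se=f.se[tsel], p=f.p[tsel], n_trials=f.n_trials, roi=roi,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        beta = np.nanmean(B, axis=0)
        n = np.sum(np.isfinite(B), axis=0)
        sd = np.nanstd(B, axis=0, ddof=1)
    se = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
    p = np.full(beta.shape, np.nan)
    fin = np.isfinite(tstat) & (n > 1)
    p[fin] = 2.0 * sps.t.sf(np.abs(tstat[fin]), n[fin] - 1)
    return TimecourseEstimate(
        site_id=f"roi:{roi}", condition=condition, time_axis=time_axis,
        beta=beta, se=se, p=np.minimum(p, 1.0),
        n_trials=int(sum(f.n_trials for f in fits)), roi=roi,
    )
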