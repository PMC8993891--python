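"""Functional specificity and self/other selectivity of mentalizing-active sites.

Specificity: a mentalizing-active site (self + other collapsed) is
'mentalizing_specific' iff it is not cognitive-active AND its single-trial
peak power (including trials with nonsignificant activations) is significantly
higher for mentalizing than for arithmetic; coactivation for both tasks makes
it 'non_specific' regardless of the power comparison, as does a nonsignificant
power excess. Selectivity: sites active for both mentalizing types are labeled
by the sign of a significant self-vs-other peak-power difference
(self_greater / other_greater / non_selective); sites active for exactly one
type are 'self_only'/'other_only' only when that type's peak power is also
significantly greater, else 'non_selective'. Peak-power comparisons use
bisquare robust regression with BY correction across sites (one family per
comparison).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .io import EffectEstimate
from .stats import bisquare_regress, fdr_by, mcnemar_yates

__all__ = [
    "SiteProfile",
    "compare_peak_power",
    "classify_specificity",
    "classify_selectivity",
    "classify_sites",
    "selectivity_counts",
]

MIN_TRIALS_PER_CONDITION = 8

SPECIFICITY_LABELS = ("mentalizing_specific", "non_specific", "not_applicable")
SELECTIVITY_LABELS = (
    "self_only", "other_only", "self_greater", "other_greater",
    "non_selective", "not_applicable",
)


@dataclass
class SiteProfile:
    """Per-site activity pattern plus peak-power comparison outcomes."""

    site_id: str
    roi: str = "none"
    participant_id: str = ""
    mentalizing_active: bool = False  # self+other collapsed trial-averaged fit
    cognitive_active: bool = False
    self_active: bool = False
    other_active: bool = False
    # mentalizing - cognitive peak power comparison
    mz_vs_cog: Optional[EffectEstimate] = None
    mz_vs_cog_sig: bool = False
    # self - other peak power comparison
    self_vs_other: Optional[EffectEstimate] = None
    self_vs_other_sig: bool = False
    specificity: str = "not_applicable"
    selectivity: str = "not_applicable"


def compare_peak_power(
    metrics: pd.DataFrame, site_id: str, conds_a, conds_b
) -> Optional[EffectEstimate]:
    """Robust regression of single-trial peak power on a condition indicator.

    The slope is the A-minus-B difference (conditions coded +1/2 vs -1/2).
    Includes trials with nonsignificant activations (their peak power is the
    valid-range maximum). Returns None when either condition has fewer than
    8 usable trials.
    """
    if isinstance(conds_a, str):
        conds_a = [conds_a]
    if isinstance(conds_b, str):
        conds_b = [conds_b]
    sub = metrics[
        (metrics["site_id"] == site_id)
        & metrics["condition"].isin(list(conds_a) + list(conds_b))
        & np.isfinite(metrics["peak_power_z"])
    ]
    in_a = sub["condition"].isin(conds_a).to_numpy()
    if in_a.sum() < MIN_TRIALS_PER_CONDITION or (~in_a).sum() < MIN_TRIALS_PER_CONDITION:
        return None
    y = sub["peak_power_z"].to_numpy(float)
    X = np.column_stack([np.ones(len(sub)), np.where(in_a, 0.5, -0.5)])
    fit = bisquare_regress(X, y)
    return EffectEstimate(
        name="peak_power_diff",
        b=float(fit.coefficients[1]),
        se=float(max(fit.se[1], 1e-12)),
        p=float(fit.p[1]),
        df=fit.df,
        method="bisquare",
    )


def classify_specificity(profile: SiteProfile) -> str:
    """Specificity label; total on mentalizing-active sites."""
    if not profile.mentalizing_active:
        return "not_applicable"
    if profile.cognitive_active:
        return "non_specific"  # coactivation wins regardless of power difference
    if (
        profile.mz_vs_cog is not None
        and profile.mz_vs_cog_sig
        and profile.mz_vs_cog.b > 0
    ):
        return "mentalizing_specific"
    return "non_specific"


def classify_selectivity(profile: SiteProfile) -> str:
    """Self/other selectivity label.

    Applicable to sites active for collapsed mentalizing or for either
    individual mentalizing type (a strictly self-only site is part of the
    selectivity population even when the collapsed fit is marginal).
    """
    if not (profile.mentalizing_active or profile.self_active or profile.other_active):
        return "not_applicable"
    cmp_sig = (
        profile.self_vs_other is not None and profile.self_vs_other_sig
    )
    diff = profile.self_vs_other.b if profile.self_vs_other is not None else 0.0
    if profile.self_active and profile.other_active:
        if cmp_sig and diff > 0:
            return "self_greater"
        if cmp_sig and diff < 0:
            return "other_greater"
        return "non_selective"
    if profile.self_active and not profile.other_active:
        return "self_only" if (cmp_sig and diff > 0) else "non_selective"
    if profile.other_active and not profile.self_active:
        return "other_only" if (cmp_sig and diff < 0) else "non_selective"
    # Collapsed-mentalizing active but neither type individually active:
    # labeled by the power comparison alone, never 'x_only'.
    return "non_selective"


def classify_sites(
    metrics: pd.DataFrame,
    labels: pd.DataFrame,
    alpha: float = 0.05,
) -> list[SiteProfile]:
    """Build and label a SiteProfile for every site in the label table.

    ``labels`` is the tidy output of trial_averaged.run_trial_averaged (one
    row per site x condition). BY correction for each peak-power family
    (mentalizing-vs-cognitive; self-vs-other) runs across sites within the
    label table's participant set.
    """
    lab = labels.pivot_table(
        index=["participant_id", "site_id", "roi"],
        columns="condition", values="label", aggfunc="first",
    ).reset_index()

    profiles = []
    for _, row in lab.iterrows():
        prof = SiteProfile(
            site_id=row["site_id"],
            roi=row["roi"],
            participant_id=row["participant_id"],
            mentalizing_active=row.get("mentalizing", "nonresponsive") == "active",
            cognitive_active=row.get("cognitive", "nonresponsive") == "active",
            self_active=row.get("self", "nonresponsive") == "active",
            other_active=row.get("other", "nonresponsive") == "active",
        )
        prof.mz_vs_cog = compare_peak_power(
            metrics, prof.site_id, ["self", "other"], ["cognitive"]
        )
        prof.self_vs_other = compare_peak_power(metrics, prof.site_id, ["self"], ["other"])
        profiles.append(prof)

    for attr, sig_attr in (("mz_vs_cog", "mz_vs_cog_sig"), ("self_vs_other", "self_vs_other_sig")):
        idx = [i for i, p in enumerate(profiles) if getattr(p, attr) is not None]
        if idx:
            adj = fdr_by([getattr(profiles[i], attr).p for i in idx])
            for j, i in enumerate(idx):
                setattr(profiles[i], sig_attr, bool(adj[j] < alpha))

    for prof in profiles:
        prof.specificity = classify_specificity(prof)
        prof.selectivity = classify_selectivity(prof)
    return profiles


def profiles_table(profiles: list[SiteProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append(
            {
                "participant_id": p.participant_id,
                "site_id": p.site_id,
                "roi": p.roi,
                "mentalizing_active": p.mentalizing_active,
                "cognitive_active": p.cognitive_active,
                "self_active": p.self_active,
                "other_active": p.other_active,
                "specificity": p.specificity,
                "selectivity": p.selectivity,
                "mz_vs_cog_b": p.mz_vs_cog.b if p.mz_vs_cog else np.nan,
                "mz_vs_cog_p": p.mz_vs_cog.p if p.mz_vs_cog else np.nan,
                "mz_vs_cog_sig": p.mz_vs_cog_sig,
                "self_vs_other_b": p.self_vs_other.b if p.self_vs_other else np.nan,
                "self_vs_other_p": p.self_vs_other.p if p.self_vs_other else np.nan,
                "self_vs_other_sig": p.self_vs_other_sig,
            }
        )
    return pd.DataFrame(rows)


def selectivity_counts(profiles: list[SiteProfile], roi: Optional[str] = None):
    """Self-selective vs other-selective site counts with McNemar chi-square.

    Self-selective = self_only + self_greater; other-selective = other_only +
    other_greater; the two counts enter the Yates-corrected McNemar test as
    the discordant cells.
    """
    pool = [p for p in profiles if roi is None or p.roi == roi]
    pool = [
        p for p in pool
        if p.mentalizing_active or p.self_active or p.other_active
    ]
    if not pool:
        raise ValueError(f"no mentalizing-active sites in ROI {roi!r}")
    n_self = sum(p.selectivity in ("self_only", "self_greater") for p in pool)
    n_other = sum(p.selectivity in ("other_only", "other_greater") for p in pool)
    return n_self, n_other, mcnemar_yates(n_self, n_other)
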