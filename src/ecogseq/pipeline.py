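"""End-to-end orchestration: simulate -> preprocess -> detect -> classify -> infer.

A single global seed fans out deterministically to stage-local streams, every
stage logs exclusion counts, and all outputs land as TSV tables plus a JSON
manifest (config + hash + seed + version), so identical (config, seed) runs
produce byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
import pandas as pd

from . import behavior as bhv
from . import classify as clf
from . import roi as roi_mod
from .io import ValidationError, write_results
from .preprocess import PreprocessConfig, preprocess_session
from .simulate import ROI_ONSET_MS, SimulationConfig, simulate_study
from .single_trial import DetectionConfig, run_single_trial
from .trial_averaged import run_trial_averaged, time_window_summary

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "analyze_session"]

#: Fixture-scale default study: 3 participants, one site per ROI, 12 trials
#: per task condition. Larger (paper-scale) runs are reached through config.
DEFAULT_SIM_OVERRIDES = {
    "n_participants": 3,
    "sites_per_roi": {r: 1 for r in ROI_ONSET_MS},
    "non_roi_sites": 24,
    "trials_per_condition": {"self": 12, "other": 12, "cognitive": 12},
}


@dataclass
class RunConfig:
    seed: int = 1
    out_dir: str = "results/pipeline"
    alpha: float = 0.05
    sim: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"config: unknown keys {sorted(unknown)}")
        cfg = cls(**d)
        for sub, target in (
            ("sim", SimulationConfig), ("detection", DetectionConfig),
            ("preprocess", PreprocessConfig),
        ):
            sub_known = {f.name for f in dataclasses.fields(target)}
            bad = set(getattr(cfg, sub)) - sub_known
            if bad:
                raise ValidationError(f"config.{sub}: unknown keys {sorted(bad)}")
        return cfg

    def as_dict(self) -> dict:
        return {
            "seed": self.seed, "out_dir": self.out_dir, "alpha": self.alpha,
            "sim": {k: str(v) for k, v in self.sim.items()},
            "detection": dict(self.detection),
            "preprocess": {k: str(v) for k, v in self.preprocess.items()},
        }

    def sim_config(self) -> SimulationConfig:
        overrides = {**DEFAULT_SIM_OVERRIDES, **self.sim}
        overrides.setdefault("seed", self.seed)
        return SimulationConfig(**overrides)


def analyze_session(recording, events, det_cfg=None, pre_cfg=None, sites=None):
    """Preprocess one session and run both within-site analyses.

    By default ROI sites plus two non-ROI reference sites are analyzed; the
    rest of the montage only serves the common average (filler electrodes
    keep the re-referencing leakage of co-active sites realistic).
    """
    if sites is None:
        roi_sites = [c.site_id for c in recording.channels if c.roi != "none"]
        none_sites = [c.site_id for c in recording.channels if c.roi == "none"][:2]
        sites = roi_sites + none_sites
    epochs = preprocess_session(recording, events, pre_cfg, sites=sites)
    metrics = run_single_trial(epochs, det_cfg)
    estimates, labels = run_trial_averaged(epochs)
    return epochs, metrics, estimates, labels


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Full simulated-study analysis; returns (and optionally writes) tables."""
    det_cfg = DetectionConfig(**config.detection)
    pre_cfg = PreprocessConfig(**config.preprocess)
    sim_cfg = config.sim_config()

    sessions = simulate_study(sim_cfg)
    all_metrics, all_labels, all_events, all_profiles, all_windows = [], [], [], [], []
    exclusions = []
    for pid, (rec, events, truth) in sessions.items():
        logger.info("analyzing %s", pid)
        epochs, metrics, estimates, labels = analyze_session(
            rec, events, det_cfg, pre_cfg
        )
        windows = time_window_summary(epochs, alpha=config.alpha)
        windows.insert(0, "participant_id", pid)
        profiles = clf.classify_sites(metrics, labels, alpha=config.alpha)
        all_metrics.append(metrics)
        all_labels.append(labels)
        all_profiles.extend(profiles)
        all_windows.append(windows)
        ev = events.df.copy()
        ev.insert(0, "participant_id", pid)
        all_events.append(ev)
        if epochs.exclusion_log is not None and len(epochs.exclusion_log):
            ex = epochs.exclusion_log.copy()
            ex.insert(0, "participant_id", pid)
            exclusions.append(ex)

    metrics = pd.concat(all_metrics, ignore_index=True)
    labels = pd.concat(all_labels, ignore_index=True)
    events = pd.concat(all_events, ignore_index=True)
    windows = pd.concat(all_windows, ignore_index=True)
    profile_table = clf.profiles_table(all_profiles)

    active_sites = profile_table.loc[
        profile_table["mentalizing_active"], "site_id"
    ].tolist()
    filtered, excluded_sites, flag_summary = roi_mod.multisite_outlier_filter(
        metrics, active_sites
    )
    logger.info(
        "outlier filter: %d sites excluded (>50%% flagged observations)",
        len(excluded_sites),
    )

    rois = [r for r in ROI_ONSET_MS if (filtered["roi"] == r).any()]
    roi_effects = roi_mod.roi_model_table(filtered, rois)
    pairwise = roi_mod.pairwise_roi_matrix(filtered, rois, "onset_ms", config.alpha)

    site_table = (
        filtered[filtered["condition"].isin(["self", "other"])]
        .groupby("site_id")
        .agg(participant_id=("participant_id", "first"), roi=("roi", "first"),
             mean_onset_ms=("onset_ms", "mean"))
        .reset_index()
        .merge(profile_table[["site_id", "specificity"]], on="site_id")
    )
    site_table["specific"] = site_table["specificity"] == "mentalizing_specific"
    onset_spec = None
    if site_table["specific"].nunique() > 1 and len(site_table) >= 4:
        onset_spec = roi_mod.onset_predicts_specificity(site_table)

    sel_rows = []
    for r in rois + [None]:
        try:
            n_self, n_other, test = clf.selectivity_counts(all_profiles, r)
        except ValueError:
            continue
        sel_rows.append(
            {"roi": r if r else "whole_brain", "n_self_selective": n_self,
             "n_other_selective": n_other, "chi2": test.statistic, "p": test.p}
        )
    selectivity = pd.DataFrame(sel_rows)

    try:
        mpfc = roi_mod.mpfc_offset_vs_rt(filtered)
    except ValueError:
        mpfc = None

    choice_res = bhv.choice_bias_model(events)
    rt_res = bhv.rt_model(events)
    behavior_rows = [e.as_dict() for e in choice_res.effects.values()]
    behavior_rows += [e.as_dict() for e in rt_res.effects.values()]
    if onset_spec is not None:
        behavior_rows.append(onset_spec.as_dict())
    if mpfc is not None:
        behavior_rows.append(mpfc.as_dict())
    model_effects = pd.DataFrame(behavior_rows)

    tables = {
        "metrics": metrics,
        "labels": labels,
        "profiles": profile_table,
        "roi_effects": roi_effects,
        "pairwise_onsets": pairwise,
        "selectivity_counts": selectivity,
        "model_effects": model_effects,
        "window_summary": windows,
        "rt_cell_means": rt_res.cell_means,
        "excluded_sites": pd.DataFrame({"site_id": excluded_sites}),
        "site_flag_summary": flag_summary,
        "trial_exclusions": (
            pd.concat(exclusions, ignore_index=True)
            if exclusions
            else pd.DataFrame(columns=["participant_id", "trial_id", "reasons"])
        ),
    }
    if write:
        write_results(tables, config.out_dir, config=config.as_dict(), seed=config.seed)
    return tables
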