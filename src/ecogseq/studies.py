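"""Canned simulation studies used to validate the pipeline end to end.

Each study simulates sessions at a fixed, documented scale, runs the full
analysis path, and reduces the outcome to a handful of numbers: detector
recovery error, null false-positive rate, reproduction of the ROI onset
ordering, and parameter recovery for the behavioral and ROI models. Problem
sizes are deliberately compact (1-2 participants, 1-5 sites per ROI, tens of
trials) so a study completes in seconds to a couple of minutes on one core.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import roi as R
from .behavior import choice_bias_model
from .preprocess import preprocess_session
from .simulate import (
    BurstSpec,
    ROI_ONSET_MS,
    RTModel,
    SimulationConfig,
    ground_truth_metrics,
    simulate_session,
)
from .single_trial import run_single_trial
from .trial_averaged import run_trial_averaged

__all__ = [
    "detector_recovery_study",
    "null_detection_study",
    "latency_ordering_study",
    "choice_recovery_study",
    "type_effect_recovery_study",
]


def _burst_all_roi(rois, onset, onset_sd, dur, dur_sd, amplitude):
    spec = {}
    for roi in rois:
        for cond in ("self", "other"):
            spec[(roi, cond)] = BurstSpec(onset, onset_sd, dur, dur_sd, amplitude, 1.0)
    return spec


def detector_recovery_study(seed: int, amplitude: float = 3.0) -> dict:
    """Single-trial detection accuracy on 50 burst trials x 10 sites.

    Bursts: onset 300 +/- 30 ms, duration 400 +/- 50 ms at the target
    amplitude, on ten ROI sites; 50 burst-free filler trials keep the burst
    duty cycle inside the calibratable regime. Returns the median absolute
    onset error (ms), median relative duration error, and the per-trial
    activation rate.
    """
    cfg = SimulationConfig(
        n_participants=1,
        sites_per_roi={"TPJ": 5, "PMC": 5},
        non_roi_sites=20,
        trials_per_condition={"self": 25, "other": 25, "cognitive": 50},
        burst_spec=_burst_all_roi(("TPJ", "PMC"), 300.0, 30.0, 400.0, 50.0, amplitude),
        cognitive_site_p={"TPJ": 0.0, "PMC": 0.0},
        rt_model=RTModel(intercept_ms=4000.0, coupling=0.0, noise_sd_ms=150.0,
                         b_vd1_ms=0.0),
        shared_duration_sd_ms=0.0,
        exclusion_rates={"hfo": 0.0, "no_response": 0.0, "irrelevant": 0.0},
        seed=int(seed),
    )
    rec, events, truth = simulate_session(cfg, "P01")
    roi_sites = [c.site_id for c in rec.channels if c.roi != "none"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        epochs = preprocess_session(rec, events, sites=roi_sites)
        metrics = run_single_trial(epochs)
    m = metrics[metrics["condition"].isin(["self", "other"])]
    truth_b = truth.bursts[truth.bursts["is_active"]]
    merged = m.merge(
        truth_b[["site_id", "trial_id", "true_onset_ms", "true_offset_ms"]],
        on=["site_id", "trial_id"],
    )
    act = merged[merged["has_activation"]]
    onset_err = float((act["onset_ms"] - act["true_onset_ms"]).abs().median())
    true_dur = act["true_offset_ms"] - act["true_onset_ms"]
    dur_err = float(((act["duration_ms"] - true_dur) / true_dur).abs().median())
    return {
        "median_onset_error_ms": onset_err,
        "median_duration_rel_error": dur_err,
        "activation_rate": float(merged["has_activation"].mean()),
        "n_trials": int(len(merged)),
    }


def null_detection_study(seed: int) -> dict:
    """False-positive control: burst-free montage through the full chain.

    Returns the fraction of sites labeled active by the trial-averaged
    analysis and the single-trial activation rate.
    """
    cfg = SimulationConfig(
        n_participants=1,
        sites_per_roi={"TPJ": 5, "PMC": 5},
        non_roi_sites=20,
        trials_per_condition={"self": 25, "other": 25, "cognitive": 50},
        burst_spec={("none", "rest"): BurstSpec(0, 0, 100, 0, 0.0, 0.0)},
        rt_model=RTModel(intercept_ms=4000.0, coupling=0.0, noise_sd_ms=150.0,
                         b_vd1_ms=0.0),
        shared_duration_sd_ms=0.0,
        exclusion_rates={"hfo": 0.0, "no_response": 0.0, "irrelevant": 0.0},
        seed=int(seed),
    )
    rec, events, _ = simulate_session(cfg, "P01")
    roi_sites = [c.site_id for c in rec.channels if c.roi != "none"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        epochs = preprocess_session(rec, events, sites=roi_sites)
        metrics = run_single_trial(epochs)
        _, labels = run_trial_averaged(epochs)
    ment = labels[labels["condition"] == "mentalizing"]
    return {
        "site_active_fraction": float((ment["label"] == "active").mean()),
        "trial_activation_rate": float(metrics["has_activation"].mean()),
        "n_sites": int(len(ment)),
    }


# ROI tiers of the expected onset ordering: visual cortex, then
# temporoparietal DMN, then amPFC/dmPFC, then vmPFC.
_TIERS = [("Visual",), ("TPJ", "ATL", "PMC"), ("amPFC", "dmPFC"), ("vmPFC",)]


def latency_ordering_study(seed: int, amplitude: float = 2.0) -> dict:
    """One seed of the cross-ROI onset-ordering reproduction.

    Two participants with one site per ROI at the default ROI onset means;
    the pairwise RT-controlled ROI model must reproduce the sign pattern
    Visual < temporoparietal < amPFC/dmPFC < vmPFC with significant
    Visual-versus-all contrasts.
    """
    spec = {}
    for roi, onset in ROI_ONSET_MS.items():
        for cond in ("self", "other"):
            spec[(roi, cond)] = BurstSpec(
                onset, 30.0, 650.0, 60.0, amplitude, 1.0
            )
    cfg = SimulationConfig(
        n_participants=2,
        sites_per_roi={r: 1 for r in ROI_ONSET_MS},
        non_roi_sites=16,
        trials_per_condition={"self": 8, "other": 8, "cognitive": 12, "episodic": 12},
        burst_spec=spec,
        cognitive_site_p={r: 0.0 for r in ROI_ONSET_MS},
        shared_duration_sd_ms=200.0,
        exclusion_rates={"hfo": 0.0, "no_response": 0.0, "irrelevant": 0.0},
        seed=int(seed),
    )
    frames = []
    for pid in ("P01", "P02"):
        rec, events, _ = simulate_session(cfg, pid)
        roi_sites = [c.site_id for c in rec.channels if c.roi != "none"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            epochs = preprocess_session(rec, events, sites=roi_sites)
            frames.append(run_single_trial(epochs))
    metrics = pd.concat(frames, ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix = R.pairwise_roi_matrix(metrics, list(ROI_ONSET_MS), "onset_ms")

    sign_ok = True
    visual_sig = True
    tier_of = {r: i for i, tier in enumerate(_TIERS) for r in tier}
    for _, row in matrix.iterrows():
        if not row["estimable"]:
            sign_ok = False
            continue
        tx, ty = tier_of[row["roi_x"]], tier_of[row["roi_y"]]
        if tx != ty and np.sign(row["b"]) != np.sign(tx - ty):
            sign_ok = False
        if "Visual" in (row["roi_x"], row["roi_y"]) and tx != ty and not row["sig"]:
            visual_sig = False
    mean_onsets = (
        metrics[np.isfinite(metrics["onset_ms"])]
        .groupby("roi")["onset_ms"].mean().to_dict()
    )
    return {"sign_ok": bool(sign_ok), "visual_sig": bool(visual_sig),
            "mean_onsets": mean_onsets}


def choice_recovery_study(seed: int, n_participants: int = 4) -> dict:
    """One replicate of choice-bias logistic recovery at fixture scale."""
    cfg = SimulationConfig(
        n_participants=n_participants,
        sites_per_roi={"TPJ": 1},
        non_roi_sites=0,
        trials_per_condition={"self": 40, "other": 40},
        seed=int(seed),
    )
    frames = []
    for i in range(n_participants):
        _, ev, _ = simulate_session(cfg, f"P{i + 1:02d}", signal=False)
        d = ev.df.copy()
        d["participant_id"] = f"P{i + 1:02d}"
        frames.append(d)
    events = pd.concat(frames, ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = choice_bias_model(events)
    val = res.effects["valence"]
    truth = cfg.choice_model.b_valence
    return {
        "b": val.b, "se": val.se, "or": val.or_value,
        "covered": bool(abs(val.b - truth) <= 2 * val.se),
    }


def type_effect_recovery_study(seed: int) -> dict:
    """One replicate of the Type (other-minus-self) duration-model recovery.

    RT is decoupled from condition in this design so the RT-controlled Type
    estimand equals the generator's direct +150 ms duration increment.
    """
    cfg = SimulationConfig(
        n_participants=2,
        sites_per_roi={"dmPFC": 2},
        non_roi_sites=0,
        trials_per_condition={"self": 25, "other": 25},
        rt_model=RTModel(intercept_ms=2500.0, coupling=0.0, noise_sd_ms=400.0,
                         b_vd1_ms=0.0),
        shared_duration_sd_ms=0.0,
        seed=int(seed),
    )
    frames = []
    for i in range(2):
        _, ev, truth = simulate_session(cfg, f"P{i + 1:02d}", signal=False)
        frames.append(ground_truth_metrics(truth, ev, seed=(int(seed) * 7 + i) % 2**31))
    metrics = pd.concat(frames, ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = R.fit_roi_type_rt_choice(metrics, "dmPFC", "duration_ms")
    e = res.effects["Type_Other-Self"]
    from .simulate import OTHER_DURATION_EXTRA_MS

    return {
        "b": e.b, "se": e.se,
        "covered": bool(abs(e.b - OTHER_DURATION_EXTRA_MS) <= 2 * e.se),
    }
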