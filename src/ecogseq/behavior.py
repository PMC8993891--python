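"""Behavioral models: the self-positivity choice bias and the RT model.

The choice model is a logistic mixed classification of choosing 'true' on
trait valence and the valence x mentalizing-type interaction (trait- and
participant-nested); valence is coded +1/2 (positive) / -1/2 (negative) and
type +1/2 (self) / -1/2 (other), so a positive interaction reads "the
positivity bias is stronger during self-mentalizing". The RT model is a
participant-nested LMEM with mentalizing type, choice, their interaction, and
the two visual-dissimilarity covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EventTable
from .mixed import fit_lmm, fit_logistic_mixed

__all__ = ["BehavioralResult", "choice_bias_model", "rt_model"]


@dataclass
class BehavioralResult:
    effects: dict = field(default_factory=dict)  # name -> EffectEstimate
    cell_means: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_trials: int = 0


def _mentalizing_events(events) -> pd.DataFrame:
    df = events.df if isinstance(events, EventTable) else events
    out = df[df["condition"].isin(["self", "other"])].copy()
    out["type_c"] = np.where(out["condition"] == "self", 0.5, -0.5)
    return out


def choice_bias_model(events, participant_col: str = "participant_id") -> BehavioralResult:
    """Valence bias in true/false choices, with its self/other interaction."""
    df = _mentalizing_events(events)
    df = df[df["choice"].isin(["true", "false"])]
    df = df[df["trait_valence"].isin(["positive", "negative"])].copy()
    if df["trait_valence"].nunique() < 2:
        raise ValueError("choice model needs both trait valences")
    if participant_col not in df.columns:
        df[participant_col] = "P01"
    df["y"] = (df["choice"] == "true").astype(int)
    df["val_c"] = np.where(df["trait_valence"] == "positive", 0.5, -0.5)
    vc = ["trait", participant_col] if df["trait"].nunique() > 1 else [participant_col]
    effects = fit_logistic_mixed(
        df,
        "y ~ val_c + type_c + val_c:type_c",
        {"val_c": "valence", "val_c:type_c": "valence_x_type"},
        vc_groups=vc,
    )
    means = (
        df.groupby(["condition", "trait_valence"])["y"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "p_true", "size": "n"})
    )
    return BehavioralResult(effects=effects, cell_means=means, n_trials=len(df))


def rt_model(events, participant_col: str = "participant_id") -> BehavioralResult:
    """RT on mentalizing type, choice, their interaction, and VD covariates."""
    df = _mentalizing_events(events)
    df = df[df["choice"].isin(["true", "false"]) & np.isfinite(df["rt_ms"])].copy()
    if participant_col not in df.columns:
        df[participant_col] = "P01"
    df["choice_c"] = np.where(df["choice"] == "true", 0.5, -0.5)
    effects = fit_lmm(
        df,
        "rt_ms ~ type_c + choice_c + type_c:choice_c + vd1 + vd2",
        {"type_c": "type_self-other", "choice_c": "choice_true-false",
         "type_c:choice_c": "type_x_choice", "vd1": "VD1", "vd2": "VD2"},
        groups=participant_col, re_formula="1",
    )
    cells = (
        df.groupby(["condition", "choice"])["rt_ms"]
        .agg(["mean", "sem", "size"])
        .reset_index()
        .rename(columns={"mean": "rt_mean_ms", "sem": "rt_sem_ms", "size": "n"})
    )
    return BehavioralResult(effects=effects, cell_means=cells, n_trials=len(df))
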