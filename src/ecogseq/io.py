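"""Canonical on-disk data model, readers/writers and validation.

A session is a directory holding ``channels.tsv``, ``events.tsv``,
``signal.bin`` (little-endian float32, channel-major) with a ``signal.json``
sidecar, and optionally ground-truth tables from the simulator. Result tables
are written as TSV with a JSON run manifest (config hash, seed, software
version, per-table schemas). Reading an EDF file via :mod:`mne` is supported
when that package is importable.

Conventions: analysis times are milliseconds relative to stimulus onset,
sample indices are 0-based, and windows are half-open ``[start, end)`` unless
stated otherwise. ``rt_ms`` is stored at 1-ms resolution.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ROIS",
    "CONDITIONS",
    "MENTALIZING_CONDITIONS",
    "ValidationError",
    "ChannelInfo",
    "Recording",
    "EventTable",
    "EffectEstimate",
    "read_session",
    "write_session",
    "write_results",
    "read_results",
]

ROIS = ("Visual", "ATL", "TPJ", "PMC", "amPFC", "dmPFC", "vmPFC", "none")
MPFC_ROIS = ("amPFC", "dmPFC", "vmPFC")
CONDITIONS = ("self", "other", "cognitive", "episodic", "semantic", "rest")
MENTALIZING_CONDITIONS = ("self", "other")
HEMISPHERES = ("L", "R", "unknown")
CHOICES = ("true", "false", "none")
VALENCES = ("positive", "negative", "none")

EVENT_COLUMNS = [
    "trial_id",
    "condition",
    "stim_onset",
    "response_sample",
    "choice",
    "trait",
    "trait_valence",
    "vd1",
    "vd2",
    "hfo_flag",
    "irrelevant_press",
]


class ValidationError(ValueError):
    """An input violated a data-model invariant; the message names the field."""


@dataclass
class ChannelInfo:
    site_id: str
    participant_id: str
    roi: str = "none"
    hemisphere: str = "unknown"
    clinically_excluded: bool = False
    mni_coords: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.roi not in ROIS:
            raise ValidationError(f"roi: unknown ROI label {self.roi!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(f"hemisphere: unknown value {self.hemisphere!r}")


@dataclass
class Recording:
    """Continuous multichannel voltage (microvolt) with channel metadata."""

    participant_id: str
    fs: float
    channels: list[ChannelInfo]
    voltage: np.ndarray  # channels x samples
    line_freq: float = 60.0

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=np.float32)
        if self.fs < 1000:
            raise ValidationError(f"fs: sampling rate must be >= 1000 Hz, got {self.fs}")
        if self.voltage.ndim != 2 or self.voltage.shape[0] != len(self.channels):
            raise ValidationError(
                "voltage: row count must equal channel count "
                f"({self.voltage.shape} vs {len(self.channels)} channels)"
            )
        if np.isnan(self.voltage).any():
            raise ValidationError("voltage: NaN values are not allowed")
        ids = [c.site_id for c in self.channels]
        if len(set(ids)) != len(ids):
            raise ValidationError("site_id: duplicate site ids within participant")

    @property
    def n_samples(self) -> int:
        return self.voltage.shape[1]

    def retained_channels(self) -> list[int]:
        """Indices of channels not flagged by clinical exclusion."""
        return [i for i, c in enumerate(self.channels) if not c.clinically_excluded]


@dataclass
class EventTable:
    """Per-trial events; wraps a validated :class:`pandas.DataFrame`.

    ``rt_ms`` is derived as ``(response_sample - stim_onset) / fs * 1000``
    rounded to the millisecond and is recomputed on construction.
    """

    df: pd.DataFrame
    fs: float

    def __post_init__(self) -> None:
        df = self.df.copy().reset_index(drop=True)
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"events: missing columns {missing}")
        if df["trial_id"].duplicated().any():
            raise ValidationError("trial_id: duplicate trial ids")
        bad = ~df["condition"].isin(CONDITIONS)
        if bad.any():
            raise ValidationError(
                f"condition: unknown values {sorted(df.loc[bad, 'condition'].unique())}"
            )
        onsets = df["stim_onset"].to_numpy()
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise ValidationError("stim_onset: must be strictly increasing")
        resp = df["response_sample"].to_numpy(dtype=float)
        has_resp = ~np.isnan(resp)
        if np.any(resp[has_resp] <= onsets[has_resp]):
            raise ValidationError("response_sample: must exceed stim_onset when present")
        if not df["choice"].isin(CHOICES).all():
            raise ValidationError("choice: values must be one of " + str(CHOICES))
        if not df["trait_valence"].isin(VALENCES).all():
            raise ValidationError("trait_valence: values must be one of " + str(VALENCES))
        rt = np.full(len(df), np.nan)
        rt[has_resp] = np.round((resp[has_resp] - onsets[has_resp]) / self.fs * 1000.0)
        df["rt_ms"] = rt
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "EventTable":
        sub = self.df.loc[mask].copy()
        return EventTable(df=sub.drop(columns=["rt_ms"]), fs=self.fs)


@dataclass
class EffectEstimate:
    """A slope estimate with its SE, two-tailed p, and effective df."""

    name: str
    b: float
    se: float
    p: float
    df: float
    or_value: Optional[float] = None
    method: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0 and math.isfinite(self.se):
            raise ValidationError(f"se: must be positive, got {self.se}")
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"p: must lie in [0, 1], got {self.p}")
        if self.or_value is not None:
            if not math.isclose(self.or_value, math.exp(self.b), rel_tol=1e-12):
                raise ValidationError("or_value: must equal exp(b) to machine precision")

    @classmethod
    def logistic(cls, name, b, se, p, df, method="") -> "EffectEstimate":
        return cls(name=name, b=b, se=se, p=p, df=df, or_value=math.exp(b), method=method)

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "b": self.b,
            "se": self.se,
            "p": self.p,
            "df": self.df,
            "or_value": self.or_value if self.or_value is not None else np.nan,
            "method": self.method,
        }


# ---------------------------------------------------------------------------
# session container

_CHANNEL_COLS = ["site_id", "participant_id", "roi", "hemisphere", "clinically_excluded",
                 "mni_x", "mni_y", "mni_z"]


def write_session(path, recording: Recording, events: EventTable, ground_truth=None) -> None:
    """Write a session directory (channels.tsv, events.tsv, signal.bin/.json)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for c in recording.channels:
        mni = c.mni_coords if c.mni_coords is not None else (np.nan, np.nan, np.nan)
        rows.append(
            [c.site_id, c.participant_id, c.roi, c.hemisphere, c.clinically_excluded, *mni]
        )
    pd.DataFrame(rows, columns=_CHANNEL_COLS).to_csv(
        path / "channels.tsv", sep="\t", index=False
    )
    events.df[EVENT_COLUMNS].to_csv(path / "events.tsv", sep="\t", index=False)
    recording.voltage.astype("<f4").tofile(path / "signal.bin")
    sidecar = {
        "participant_id": recording.participant_id,
        "fs": recording.fs,
        "line_freq": recording.line_freq,
        "n_channels": recording.voltage.shape[0],
        "n_samples": recording.voltage.shape[1],
        "dtype": "<f4",
        "order": "channel-major",
    }
    (path / "signal.json").write_text(json.dumps(sidecar, indent=2))
    if ground_truth is not None:
        ground_truth.write(path)


def _read_channels(path: Path) -> list[ChannelInfo]:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "participant_id": str})
    channels = []
    for _, r in df.iterrows():
        mni = None
        if not (pd.isna(r["mni_x"]) or pd.isna(r["mni_y"]) or pd.isna(r["mni_z"])):
            mni = (float(r["mni_x"]), float(r["mni_y"]), float(r["mni_z"]))
        channels.append(
            ChannelInfo(
                site_id=str(r["site_id"]),
                participant_id=str(r["participant_id"]),
                roi=str(r["roi"]),
                hemisphere=str(r["hemisphere"]),
                clinically_excluded=bool(r["clinically_excluded"]),
                mni_coords=mni,
            )
        )
    return channels


def read_session(path) -> tuple[Recording, EventTable]:
    """Load and validate a session directory written by :func:`write_session`.

    Also accepts a directory holding an EDF file (``signal.edf``) plus the two
    TSV tables, if :mod:`mne` is available.
    """
    path = Path(path)
    for fname in ("channels.tsv", "events.tsv"):
        if not (path / fname).exists():
            raise FileNotFoundError(f"session is missing {fname} in {path}")
    channels = _read_channels(path / "channels.tsv")

    if (path / "signal.json").exists():
        sidecar = json.loads((path / "signal.json").read_text())
        raw = np.fromfile(path / "signal.bin", dtype=sidecar.get("dtype", "<f4"))
        voltage = raw.reshape(sidecar["n_channels"], sidecar["n_samples"])
        fs = float(sidecar["fs"])
        recording = Recording(
            participant_id=sidecar["participant_id"],
            fs=fs,
            channels=channels,
            voltage=voltage,
            line_freq=float(sidecar.get("line_freq", 60.0)),
        )
    elif (path / "signal.edf").exists():
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise FileNotFoundError(
                "EDF session found but mne is not installed"
            ) from exc
        raw = mne.io.read_raw_edf(path / "signal.edf", preload=True, verbose="error")
        recording = Recording(
            participant_id=channels[0].participant_id if channels else "unknown",
            fs=float(raw.info["sfreq"]),
            channels=channels,
            voltage=raw.get_data() * 1e6,  # volts -> microvolts
        )
    else:
        raise FileNotFoundError(f"session is missing signal container in {path}")

    events_df = pd.read_csv(
        path / "events.tsv",
        sep="\t",
        dtype={"trait": str, "condition": str, "choice": str, "trait_valence": str},
    )
    events_df["trait"] = events_df["trait"].fillna("")
    events = EventTable(df=events_df, fs=recording.fs)
    return recording, events


# ---------------------------------------------------------------------------
# result tables + manifest

try:  # version recorded in manifests
    from importlib.metadata import version as _pkg_version

    _VERSION = _pkg_version("ecogseq")
except Exception:  # pragma: no cover
    _VERSION = "unknown"


def config_hash(config: Mapping) -> str:
    """Stable sha256 of a JSON-serialisable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_results(tables: Mapping[str, pd.DataFrame], path, config=None, seed=None) -> None:
    """Write result tables as TSV plus a JSON run manifest.

    The manifest records the software version, the seed, the configuration and
    its hash, and a per-table column/dtype schema so tables round-trip typed.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    schemas = {}
    for name, df in tables.items():
        df.to_csv(path / f"{name}.tsv", sep="\t", index=False)
        schemas[name] = {c: str(t) for c, t in df.dtypes.items()}
    manifest = {
        "version": _VERSION,
        "seed": seed,
        "config": config if config is not None else {},
        "config_hash": config_hash(config or {}),
        "schemas": schemas,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def read_results(path) -> dict[str, pd.DataFrame]:
    """Reload tables written by :func:`write_results`, restoring dtypes."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    out = {}
    for name, schema in manifest["schemas"].items():
        df = pd.read_csv(path / f"{name}.tsv", sep="\t")
        for col, dtype in schema.items():
            if col in df.columns and len(df):
                try:
                    df[col] = df[col].astype(dtype)
                except (TypeError, ValueError):
                    pass
            elif col in df.columns:
                df[col] = df[col].astype(dtype, errors="ignore")
        out[name] = df
    return out
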