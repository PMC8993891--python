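"""Raw voltage -> baseline-corrected, smoothed high-frequency broadband epochs.

Fixed pipeline order: notch filtering of line noise and harmonics, common
average re-referencing over clinically retained channels, 5-cycle Morlet
time-frequency decomposition, per-band z-transform across the recording,
epoching to [-200, 5000) ms around stimulus onset, per-trial per-band baseline
correction over [-200, 0) ms, averaging of the 70-180 Hz bands into a single
HFB trace, and gaussian temporal smoothing (50 ms window). Timepoints after
RT + 200 ms (the next trial's territory) and cross-trial amplitude outliers
(> 3 scaled MADs within a timepoint x condition cell) are marked invalid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .io import EventTable, Recording, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "HFBEpochs",
    "default_band_centers",
    "notch_filter",
    "rereference_common_average",
    "band_z_power",
    "hfb_power",
    "epoch_baseline_smooth",
    "apply_trial_exclusions",
    "mask_timepoint_outliers",
    "preprocess_session",
]


@dataclass
class PreprocessConfig:
    notch_bands: Sequence[tuple] = ((57.0, 63.0), (117.0, 123.0), (177.0, 183.0))
    hfb_range: tuple = (70.0, 180.0)
    n_cycles: float = 5.0
    smooth_ms: float = 50.0  # total gaussian window support; sigma = smooth_ms / 6
    baseline_ms: tuple = (-200.0, 0.0)
    epoch_ms: tuple = (-200.0, 5000.0)
    rt_min_ms: float = 400.0
    post_rt_ms: float = 200.0  # validity extends to rt + post_rt_ms
    pad_s: float = 2.0  # reflection padding for filters/wavelets
    bands: Optional[Sequence[float]] = None  # analysis band centers (Hz)
    outlier_mad: float = 3.0
    outlier_min_trials: int = 5

    def band_centers(self) -> np.ndarray:
        if self.bands is not None:
            return np.asarray(self.bands, dtype=float)
        return default_band_centers()

    def hfb_centers(self) -> np.ndarray:
        c = self.band_centers()
        lo, hi = self.hfb_range
        return c[(c >= lo) & (c <= hi)]


def default_band_centers() -> np.ndarray:
    """4-200 Hz analysis grid: 1-Hz steps to 16 Hz, 3-Hz to 70, 10-Hz to 180."""
    low = np.arange(4.0, 16.0 + 1e-9, 1.0)
    mid = np.arange(19.0, 70.0 - 1e-9, 3.0)
    high = np.arange(70.0, 180.0 + 1e-9, 10.0)
    return np.concatenate([low, mid, high])


@dataclass
class HFBEpochs:
    """Site x trial x time z-scored HFB power with validity bookkeeping."""

    sites: list  # ChannelInfo, post-exclusion
    trials: pd.DataFrame  # EventTable rows surviving exclusions
    hfb: np.ndarray  # (site, trial, time) float32, gaussian-smoothed
    time_axis: np.ndarray  # ms relative to stimulus onset
    valid_mask: np.ndarray  # (site, trial, time) bool
    fs: float
    hfb_raw: Optional[np.ndarray] = None  # unsmoothed HFB for the sliding tests
    baseline_window: tuple = (-200.0, 0.0)
    band_definition: np.ndarray = field(default_factory=lambda: np.array([]))
    exclusion_log: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.hfb.shape != self.valid_mask.shape:
            raise ValidationError("valid_mask: shape must match hfb")
        if self.hfb.shape[2] != self.time_axis.size:
            raise ValidationError("time_axis: length must match hfb time dimension")

    @property
    def step_ms(self) -> float:
        return 1000.0 / self.fs

    def site_index(self, site_id: str) -> int:
        for i, c in enumerate(self.sites):
            if c.site_id == site_id:
                return i
        raise KeyError(site_id)

    def condition_mask(self, conditions) -> np.ndarray:
        if isinstance(conditions, str):
            conditions = [conditions]
        return self.trials["condition"].isin(conditions).to_numpy()


# ---------------------------------------------------------------------------
# filtering and re-referencing

def _reflect_pad(x: np.ndarray, pad: int) -> np.ndarray:
    pad = min(pad, x.shape[-1] - 1)
    return np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect"), pad


def notch_filter(recording: Recording, bands=None) -> Recording:
    """Zero-phase band-stop filtering of line noise and harmonics per channel."""
    bands = bands if bands is not None else PreprocessConfig().notch_bands
    nyq = recording.fs / 2.0
    v = recording.voltage.astype(np.float64)
    pad = int(2.0 * recording.fs)
    for lo, hi in bands:
        if hi >= nyq:
            raise ValidationError(f"notch band edge {hi} Hz >= Nyquist {nyq} Hz")
        sos = spsig.butter(4, [lo, hi], btype="bandstop", fs=recording.fs, output="sos")
        vp, p = _reflect_pad(v, pad)
        v = spsig.sosfiltfilt(sos, vp, axis=-1)[..., p:p + recording.n_samples]
    return Recording(
        participant_id=recording.participant_id,
        fs=recording.fs,
        channels=list(recording.channels),
        voltage=v,
        line_freq=recording.line_freq,
    )


def rereference_common_average(recording: Recording) -> Recording:
    """Subtract the mean of retained channels; excluded channels are dropped."""
    keep = recording.retained_channels()
    if len(keep) < 2:
        raise ValidationError("rereference: need at least 2 retained channels")
    v = recording.voltage[keep].astype(np.float64)
    v = v - v.mean(axis=0, keepdims=True)
    return Recording(
        participant_id=recording.participant_id,
        fs=recording.fs,
        channels=[recording.channels[i] for i in keep],
        voltage=v,
        line_freq=recording.line_freq,
    )


# ---------------------------------------------------------------------------
# time-frequency decomposition

def band_z_power(
    x: np.ndarray, fs: float, centers, n_cycles: float = 5.0, pad_s: float = 2.0
) -> np.ndarray:
    """Morlet-wavelet band power, z-scored across time, per analysis band.

    The n-cycle Morlet filter is applied in the frequency domain as a gaussian
    magnitude response centered at fc with sigma_f = fc / n_cycles (the exact
    spectrum of the time-domain wavelet); the squared magnitude of the analytic
    output is the band power.
    """
    x = np.asarray(x, dtype=float)
    centers = np.atleast_1d(np.asarray(centers, dtype=float))
    fc_min = centers.min()
    if x.size < 10 * fs / fc_min * 1.0:
        raise ValidationError(
            "recording shorter than 10 periods of the longest analysis wavelet"
        )
    pad = int(pad_s * fs)
    xp, pad = _reflect_pad(x[None, :], pad)
    xp = xp[0]
    n = xp.size
    spec = np.fft.fft(xp)
    freqs = np.fft.fftfreq(n, 1.0 / fs)
    out = np.empty((centers.size, x.size), dtype=np.float64)
    pos = freqs > 0
    for bi, fc in enumerate(centers):
        sigma_f = fc / n_cycles
        h = np.zeros(n)
        h[pos] = 2.0 * np.exp(-0.5 * ((freqs[pos] - fc) / sigma_f) ** 2)
        analytic = np.fft.ifft(spec * h)
        power = np.abs(analytic[pad:pad + x.size]) ** 2
        mu = power.mean()
        sd = power.std()
        out[bi] = (power - mu) / sd if sd > 0 else power - mu
    return out


def hfb_power(recording: Recording, config: Optional[PreprocessConfig] = None) -> np.ndarray:
    """Continuous HFB z-power per channel (mean of z-scored 70-180 Hz bands)."""
    config = config or PreprocessConfig()
    centers = config.hfb_centers()
    out = np.empty((len(recording.channels), recording.n_samples))
    for ci in range(len(recording.channels)):
        bz = band_z_power(
            recording.voltage[ci], recording.fs, centers, config.n_cycles, config.pad_s
        )
        out[ci] = bz.mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# epoching

def _gaussian_kernel(smooth_ms: float, fs: float) -> np.ndarray:
    sigma = smooth_ms / 6.0 * fs / 1000.0  # window "width" read as total support
    half = int(round(smooth_ms / 2.0 * fs / 1000.0))
    t = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (t / sigma) ** 2)
    return k / k.sum()


def _nan_smooth(rows: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Mask-normalised gaussian smoothing; NaNs neither contribute nor spread."""
    valid = np.isfinite(rows)
    filled = np.where(valid, rows, 0.0)
    num = spsig.convolve(filled, kernel[None, :], mode="same")
    den = spsig.convolve(valid.astype(float), kernel[None, :], mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = num / den
    sm[den < 1e-6] = np.nan
    sm[~valid] = np.nan
    return sm


def epoch_baseline_smooth(
    band_z: np.ndarray,
    events: EventTable,
    fs: float,
    config: Optional[PreprocessConfig] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Epoch one channel's per-band z power into smoothed HFB trials.

    ``band_z`` is (n_bands, n_samples) z-scored power for the HFB analysis
    bands. Baseline correction is per trial per band (mean over [-200, 0) ms
    subtracted) before bands are averaged and smoothed. Returns
    ``(hfb, hfb_raw, valid, time_axis, dropped_trial_ids)`` with ``hfb``
    (smoothed) and ``hfb_raw`` (pre-smoothing, for the sliding-window tests
    whose sample-level variance estimates smoothing would destroy) shaped
    (n_trials_kept, n_times). Trials whose valid span (through RT + 200 ms)
    extends past the recording end are dropped with a warning; the remainder
    of an epoch past the recording end is clipped (NaN, invalid).
    """
    config = config or PreprocessConfig()
    band_z = np.atleast_2d(band_z)
    n_samples = band_z.shape[1]
    e0, e1 = config.epoch_ms
    b0, b1 = config.baseline_ms
    s0 = int(round(e0 * fs / 1000.0))
    s1 = int(round(e1 * fs / 1000.0))
    n_t = s1 - s0
    time_axis = (np.arange(s0, s1) * 1000.0 / fs)
    bsel = (time_axis >= b0) & (time_axis < b1)
    kernel = _gaussian_kernel(config.smooth_ms, fs)

    hfb_rows, raw_rows, valid_rows, dropped = [], [], [], []
    for _, tr in events.df.iterrows():
        stim = int(tr["stim_onset"])
        rt = tr["rt_ms"]
        if not np.isfinite(rt):
            dropped.append(int(tr["trial_id"]))
            continue
        valid_end = stim + int(round((rt + config.post_rt_ms) * fs / 1000.0))
        if stim + s0 < 0 or valid_end > n_samples:
            warnings.warn(
                f"trial {tr['trial_id']}: epoch extends past recording bounds; dropped",
                stacklevel=2,
            )
            dropped.append(int(tr["trial_id"]))
            continue
        lo = stim + s0
        hi = min(stim + s1, n_samples)
        seg = np.full((band_z.shape[0], n_t), np.nan)
        seg[:, : hi - lo] = band_z[:, lo:hi]
        base = np.nanmean(seg[:, bsel], axis=1, keepdims=True)
        seg = seg - base
        raw = seg.mean(axis=0)  # bands share the NaN pattern
        trace = _nan_smooth(raw[None, :], kernel)[0]
        valid = np.isfinite(trace)
        valid &= time_axis < (rt + config.post_rt_ms)
        hfb_rows.append(trace)
        raw_rows.append(raw)
        valid_rows.append(valid)

    if hfb_rows:
        hfb = np.asarray(hfb_rows, dtype=np.float32)
        raw = np.asarray(raw_rows, dtype=np.float32)
        valid = np.asarray(valid_rows, dtype=bool)
    else:
        hfb = np.empty((0, n_t), dtype=np.float32)
        raw = np.empty((0, n_t), dtype=np.float32)
        valid = np.empty((0, n_t), dtype=bool)
    return hfb, raw, valid, time_axis, dropped


# ---------------------------------------------------------------------------
# exclusions

EXCLUSION_RULES = ("rest_condition", "hfo", "no_response", "irrelevant_press", "rt_min")


def apply_trial_exclusions(
    events: EventTable,
    rt_min_ms: float = 400.0,
    drop_rest: bool = True,
) -> tuple[EventTable, pd.DataFrame]:
    """Remove trials failing any behavioral/artifact rule; log reasons per trial.

    Rules: epileptic high-frequency oscillations, missing behavioral response,
    irrelevant button press, RT below ``rt_min_ms`` (strictly under; a trial at
    exactly the threshold is retained), and - for task analyses - the cued-rest
    condition.
    """
    df = events.df
    reasons = []
    keep = np.ones(len(df), dtype=bool)
    for i, (_, tr) in enumerate(df.iterrows()):
        why = []
        if drop_rest and tr["condition"] == "rest":
            why.append("rest_condition")
        if tr["hfo_flag"]:
            why.append("hfo")
        if not np.isfinite(tr["rt_ms"]):
            why.append("no_response")
        if tr["irrelevant_press"]:
            why.append("irrelevant_press")
        if np.isfinite(tr["rt_ms"]) and tr["rt_ms"] < rt_min_ms:
            why.append("rt_min")
        if why:
            keep[i] = False
            reasons.append((int(tr["trial_id"]), ";".join(why)))
    log = pd.DataFrame(reasons, columns=["trial_id", "reasons"])
    if not keep.any():
        warnings.warn("all trials excluded", stacklevel=2)
    kept = events.subset(keep)
    logger.info("trial exclusions: %d of %d removed", (~keep).sum(), len(df))
    return kept, log


def mask_timepoint_outliers(
    epochs: HFBEpochs, threshold: float = 3.0, min_trials: int = 5
) -> HFBEpochs:
    """Invalidate observations > threshold scaled MADs from the cross-trial
    median of the same (site, condition, timepoint) cell.

    Cells with MAD = 0 or fewer than ``min_trials`` valid trials are skipped
    (a warning is emitted once per under-populated condition).
    """
    hfb = epochs.hfb
    valid = epochs.valid_mask.copy()
    conditions = epochs.trials["condition"].to_numpy()
    for cond in np.unique(conditions):
        tsel = conditions == cond
        if tsel.sum() < min_trials:
            warnings.warn(
                f"condition {cond!r} has < {min_trials} trials; outlier masking skipped",
                stacklevel=2,
            )
            continue
        for s in range(hfb.shape[0]):
            block = np.where(valid[s, tsel], hfb[s, tsel].astype(float), np.nan)
            n_valid = np.sum(np.isfinite(block), axis=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                med = np.nanmedian(block, axis=0)
                mad = 1.4826 * np.nanmedian(np.abs(block - med), axis=0)
            usable = (n_valid >= min_trials) & (mad > 0)
            dev = np.abs(block - med)
            flag = usable[None, :] & (dev > threshold * mad[None, :])
            flag &= np.isfinite(block)
            vm = valid[s, tsel]
            vm[flag] = False
            valid[s, tsel] = vm
    return HFBEpochs(
        sites=epochs.sites,
        trials=epochs.trials,
        hfb=epochs.hfb,
        time_axis=epochs.time_axis,
        valid_mask=valid,
        fs=epochs.fs,
        hfb_raw=epochs.hfb_raw,
        baseline_window=epochs.baseline_window,
        band_definition=epochs.band_definition,
        exclusion_log=epochs.exclusion_log,
    )


# ---------------------------------------------------------------------------
# full chain

def preprocess_session(
    recording: Recording,
    events: EventTable,
    config: Optional[PreprocessConfig] = None,
    sites: Optional[Sequence[str]] = None,
) -> HFBEpochs:
    """Run the full preprocessing chain on one session.

    Channels are processed one at a time so that per-band continuous power
    never has to be held in memory for the whole montage. ``sites`` restricts
    the expensive time-frequency stage to a subset of site ids; the common
    average is always computed over the full retained montage first.
    """
    config = config or PreprocessConfig()
    rec = notch_filter(recording, config.notch_bands)
    rec = rereference_common_average(rec)
    kept_events, log = apply_trial_exclusions(events, config.rt_min_ms)

    if sites is not None:
        keep = [i for i, c in enumerate(rec.channels) if c.site_id in set(sites)]
        rec = Recording(
            participant_id=rec.participant_id, fs=rec.fs,
            channels=[rec.channels[i] for i in keep], voltage=rec.voltage[keep],
            line_freq=rec.line_freq,
        )

    centers = config.hfb_centers()
    hfb_all, raw_all, valid_all = [], [], []
    kept_trials: Optional[set] = None
    for ci in range(len(rec.channels)):
        bz = band_z_power(rec.voltage[ci], rec.fs, centers, config.n_cycles, config.pad_s)
        hfb, raw, valid, time_axis, dropped = epoch_baseline_smooth(
            bz, kept_events, rec.fs, config
        )
        hfb_all.append(hfb)
        raw_all.append(raw)
        valid_all.append(valid)
        if kept_trials is None:
            kept_trials = set(kept_events.df["trial_id"]) - set(dropped)

    trial_sel = kept_events.df["trial_id"].isin(kept_trials or set())
    trials = kept_events.df.loc[trial_sel].reset_index(drop=True)
    epochs = HFBEpochs(
        sites=list(rec.channels),
        trials=trials,
        hfb=np.asarray(hfb_all, dtype=np.float32),
        time_axis=time_axis,
        valid_mask=np.asarray(valid_all, dtype=bool),
        fs=rec.fs,
        hfb_raw=np.asarray(raw_all, dtype=np.float32),
        baseline_window=tuple(config.baseline_ms),
        band_definition=centers,
        exclusion_log=log,
    )
    return mask_timepoint_outliers(
        epochs, threshold=config.outlier_mad, min_trials=config.outlier_min_trials
    )
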