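"""Ground-truthed synthetic iEEG sessions.

Generates continuous voltage as pink (1/f^a) background plus power-line
sinusoid plus per-trial high-frequency (70-180 Hz) band-limited noise bursts
with trapezoidal envelopes, together with a behavioral event table whose
response times are coupled to the latest burst offset and whose true/false
choices follow a logistic valence-bias model. Every draw is reproducible from
(config, seed); each (participant, site) pair gets its own pseudorandom
stream, so adding sites never perturbs existing draws.

Burst carriers are spectrally shaped like the background within 70-180 Hz and
scaled so that the mean baseline-corrected HFB z inside a burst approximates
the configured target amplitude after the full preprocessing pipeline. Because
per-band power is z-scored over the whole recording, a sustained elevation of
z = a occupying duty fraction f of the recording is only achievable when
a^2 * f * (2 - f) < 1; the generator solves a per-channel variance-inflation
quadratic to compensate and falls back to the bounded-best scale (flagged in
the ground truth) when the target is unattainable.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    CONDITIONS,
    ChannelInfo,
    EventTable,
    Recording,
    ValidationError,
)

__all__ = [
    "BurstSpec",
    "RTModel",
    "ChoiceModel",
    "VDModel",
    "SimulationConfig",
    "GroundTruth",
    "simulate_session",
    "simulate_study",
    "make_fixture",
    "ground_truth_metrics",
    "FIXTURE_NAMES",
]

HFB_BAND = (70.0, 180.0)

#: ROI mean activation-onset latencies (ms) defining the default spatiotemporal
#: ordering: visual cortex earliest, temporoparietal regions mid-latency,
#: medial prefrontal regions latest.
ROI_ONSET_MS = {
    "Visual": 101.0,
    "TPJ": 303.0,
    "ATL": 316.0,
    "PMC": 322.0,
    "amPFC": 465.0,
    "dmPFC": 466.0,
    "vmPFC": 537.0,
}

# Realistic trial-level parameters the source statistics do not pin down:
# burst durations grow along the hierarchy (mPFC activity is the most
# sustained), onset jitter is small in visual cortex and larger elsewhere.
ROI_DURATION_MS = {
    "Visual": 500.0,
    "TPJ": 650.0,
    "ATL": 650.0,
    "PMC": 700.0,
    "amPFC": 800.0,
    "dmPFC": 850.0,
    "vmPFC": 900.0,
}
ROI_ONSET_SD_MS = {
    "Visual": 15.0,
    "TPJ": 50.0,
    "ATL": 50.0,
    "PMC": 50.0,
    "amPFC": 60.0,
    "dmPFC": 60.0,
    "vmPFC": 70.0,
}

#: Probability that a mentalizing-active site in each ROI also responds to the
#: arithmetic (cognitive) task: one minus the mentalizing-specific proportion
#: along the visual-to-mPFC specificity gradient.
ROI_COGNITIVE_P = {
    "Visual": 0.99,
    "TPJ": 0.62,
    "ATL": 0.68,
    "PMC": 0.42,
    "amPFC": 0.13,
    "dmPFC": 0.06,
    "vmPFC": 0.0,
}

#: Duration increment (ms) for other- over self-mentalizing bursts: other-
#: mentalizing evokes longer activations at matched onsets.
OTHER_DURATION_EXTRA_MS = 150.0

#: Loading of each ROI's burst duration on the shared per-trial processing-time
#: factor. Later hierarchy stages track the behavioral response more tightly,
#: so their activity stretches more on slow trials.
ROI_RT_TRACKING = {
    "Visual": 0.10,
    "TPJ": 0.45,
    "ATL": 0.40,
    "PMC": 0.45,
    "amPFC": 0.70,
    "dmPFC": 0.75,
    "vmPFC": 0.85,
}

_TRAITS = [
    ("honest", "positive"), ("kind", "positive"), ("generous", "positive"),
    ("smart", "positive"), ("funny", "positive"), ("brave", "positive"),
    ("loyal", "positive"), ("patient", "positive"), ("creative", "positive"),
    ("friendly", "positive"), ("reliable", "positive"), ("humble", "positive"),
    ("lazy", "negative"), ("rude", "negative"), ("selfish", "negative"),
    ("jealous", "negative"), ("messy", "negative"), ("stubborn", "negative"),
    ("anxious", "negative"), ("greedy", "negative"), ("forgetful", "negative"),
    ("impatient", "negative"), ("clumsy", "negative"), ("moody", "negative"),
]


@dataclass
class BurstSpec:
    """Trial-level burst parameters for one (ROI, condition) cell."""

    onset_mean_ms: float
    onset_sd_ms: float
    duration_mean_ms: float
    duration_sd_ms: float
    amplitude: float  # target baseline-corrected HFB z
    active_probability: float = 1.0

    def __post_init__(self) -> None:
        if self.onset_sd_ms < 0 or self.duration_sd_ms < 0:
            raise ValidationError("burst_spec: standard deviations must be >= 0")
        if not (0.0 <= self.active_probability <= 1.0):
            raise ValidationError("active_probability: must lie in [0, 1]")


@dataclass
class RTModel:
    """RT = intercept + coupling * latest burst offset + vd1 slope + noise, floored."""

    intercept_ms: float = 1050.0
    coupling: float = 1.0
    noise_sd_ms: float = 150.0
    b_vd1_ms: float = 150.0
    floor_ms: float = 400.0


@dataclass
class ChoiceModel:
    """P(true) = logistic(b_valence * val + b_valence_x_type * val * type).

    Valence is coded +1/2 (positive) / -1/2 (negative) and mentalizing type
    +1/2 (self) / -1/2 (other), so the defaults reproduce a positivity bias
    (OR = exp(0.931) = 2.53) that is stronger for self-mentalizing
    (interaction OR = exp(0.326) = 1.38).
    """

    b_valence: float = 0.931
    b_valence_x_type: float = 0.326


@dataclass
class VDModel:
    """Visual-dissimilarity covariates; vd1 tracks prompt length (other > self)."""

    vd1_mean: Mapping[str, float] = field(
        default_factory=lambda: {"self": -0.5, "other": 0.5}
    )
    vd1_sd: float = 1.0
    vd2_sd: float = 1.0


@dataclass
class SimulationConfig:
    n_participants: int = 16
    sites_per_roi: Mapping[str, int] = field(
        default_factory=lambda: {r: 5 for r in ROI_ONSET_MS}
    )
    non_roi_sites: int = 10
    trials_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {
            "self": 50, "other": 50, "cognitive": 80,
            "episodic": 50, "semantic": 50, "rest": 72,
        }
    )
    fs: float = 1000.0
    background_exponent: float = 2.0  # PSD ~ 1/f^exponent
    background_amp_uv: float = 50.0
    line_amp_uv: float = 5.0
    line_freq: float = 60.0
    burst_spec: Mapping[tuple, BurstSpec] = field(default_factory=dict)
    cognitive_site_p: Mapping[str, float] = field(
        default_factory=lambda: dict(ROI_COGNITIVE_P)
    )
    rt_model: RTModel = field(default_factory=RTModel)
    #: per-trial processing-speed jitter shared across sites (ms of duration)
    shared_duration_sd_ms: float = 400.0
    rt_tracking: Mapping[str, float] = field(
        default_factory=lambda: dict(ROI_RT_TRACKING)
    )
    choice_model: ChoiceModel = field(default_factory=ChoiceModel)
    vd_model: VDModel = field(default_factory=VDModel)
    exclusion_rates: Mapping[str, float] = field(
        default_factory=lambda: {"hfo": 0.02, "no_response": 0.01, "irrelevant": 0.01}
    )
    iti_ms: float = 200.0
    timeout_ms: float = 4000.0
    lead_ms: float = 3000.0
    tail_ms: float = 2500.0
    ramp_ms: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 1000:
            raise ValidationError("fs: must be >= 1000 Hz")
        if not self.burst_spec:
            self.burst_spec = default_burst_spec()
        for key, spec in self.burst_spec.items():
            if not isinstance(spec, BurstSpec):
                self.burst_spec[key] = BurstSpec(**spec)  # type: ignore[index]


def default_burst_spec(amplitude: float = 3.0) -> dict:
    """Default (ROI, condition) burst table following the ROI onset ordering."""
    spec = {}
    for roi, onset in ROI_ONSET_MS.items():
        dur = ROI_DURATION_MS[roi]
        sd = ROI_ONSET_SD_MS[roi]
        spec[(roi, "self")] = BurstSpec(onset, sd, dur, 80.0, amplitude, 0.9)
        spec[(roi, "other")] = BurstSpec(
            onset, sd, dur + OTHER_DURATION_EXTRA_MS, 80.0, amplitude, 0.9
        )
        # Cognitive bursts are gated per site by cognitive_site_p.
        cog_dur = 400.0 if roi != "Visual" else dur
        spec[(roi, "cognitive")] = BurstSpec(onset, sd, cog_dur, 80.0, amplitude, 0.9)
    return spec


@dataclass
class GroundTruth:
    """True burst parameters and latent behavioral drivers for one session."""

    sites: pd.DataFrame   # site_id, roi, cognitive_responsive, calib_k, calib_feasible
    bursts: pd.DataFrame  # site_id, trial_id, condition, true_onset_ms, ...
    trials: pd.DataFrame  # trial_id, latest_offset_ms, rt_latent_ms, p_true

    def write(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.sites.to_csv(path / "truth_sites.tsv", sep="\t", index=False)
        self.bursts.to_csv(path / "truth_bursts.tsv", sep="\t", index=False)
        self.trials.to_csv(path / "truth_trials.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "GroundTruth":
        path = Path(path)
        return cls(
            sites=pd.read_csv(path / "truth_sites.tsv", sep="\t"),
            bursts=pd.read_csv(path / "truth_bursts.tsv", sep="\t"),
            trials=pd.read_csv(path / "truth_trials.tsv", sep="\t"),
        )


# ---------------------------------------------------------------------------
# pseudorandom streams

def _crc(s: str) -> int:
    return zlib.crc32(s.encode()) & 0xFFFFFFFF


def _stream(seed: int, *ids: str) -> np.random.Generator:
    """Independent generator derived by hashing (seed, ids); platform stable."""
    entropy = [int(seed) & 0x7FFFFFFF] + [_crc(i) for i in ids]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------------
# signal primitives

def pink_noise(n: int, fs: float, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with power spectral density ~ 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.zeros_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def band_noise(
    n: int, fs: float, f_lo: float, f_hi: float, exponent: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance band-limited noise spectrally shaped like the background."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.zeros_like(f)
    sel = (f >= f_lo) & (f <= f_hi)
    scale[sel] = f[sel] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_variance(x: np.ndarray, fs: float, f_lo: float, f_hi: float) -> float:
    """Variance of the component of x inside [f_lo, f_hi]."""
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, 1.0 / fs)
    spec[(f < f_lo) | (f > f_hi)] = 0.0
    return float(np.fft.irfft(spec, x.size).var())


def trapezoid_envelope(n: int, ramp: int) -> np.ndarray:
    e = np.ones(n)
    r = min(ramp, n // 2)
    if r > 0:
        e[:r] = np.arange(1, r + 1) / r
        e[n - r:] = np.arange(r, 0, -1) / r
    return e


def _calibration_gain(bursts: pd.DataFrame, n_samples: int, fs: float, ramp_ms: float):
    """Gain k such that in-burst z matches the target after z-normalisation.

    Solves k^2 * (1 - (2*m2 - m1^2)) - 2*m1*k - 1 = 0 where m1, m2 are the
    first two moments of the amplitude-weighted squared-envelope duty pattern.
    Returns (k, feasible).
    """
    if not len(bursts):
        return 1.0, True
    ramp_s = int(round(ramp_ms * fs / 1000.0))
    s1 = 0.0
    s2 = 0.0
    for a, dur in zip(bursts["true_amplitude"], bursts["true_offset_ms"] - bursts["true_onset_ms"]):
        n = max(int(round(dur * fs / 1000.0)), 2)
        e2 = trapezoid_envelope(n, ramp_s) ** 2
        s1 += a * e2.sum()
        s2 += a**2 * (e2**2).sum()
    m1 = s1 / n_samples
    m2 = s2 / n_samples
    a_coef = 1.0 - (2.0 * m2 - m1**2)
    feasible = a_coef > 0.05
    a_coef = max(a_coef, 0.05)
    k = (m1 + np.sqrt(m1**2 + a_coef)) / a_coef
    return float(k), bool(feasible)


# ---------------------------------------------------------------------------
# session planning

def _plan_channels(config: SimulationConfig, participant: str) -> pd.DataFrame:
    rows = []
    for roi, count in config.sites_per_roi.items():
        for i in range(count):
            rows.append((f"{participant}-{roi}-{i:02d}", roi))
    for i in range(config.non_roi_sites):
        rows.append((f"{participant}-X-{i:02d}", "none"))
    df = pd.DataFrame(rows, columns=["site_id", "roi"])
    # per-site stream: adding sites must not perturb other sites' draws
    df["cognitive_responsive"] = [
        _stream(config.seed, participant, sid, "profile").random()
        < config.cognitive_site_p.get(roi, 0.0)
        for sid, roi in zip(df["site_id"], df["roi"])
    ]
    return df


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _plan_session(config: SimulationConfig, participant: str):
    """Draw events, per-site bursts and latent behavior for one participant."""
    fs = config.fs
    p_rng = _stream(config.seed, participant, "events")
    sites = _plan_channels(config, participant)
    site_rngs = {
        s: _stream(config.seed, participant, s, "bursts") for s in sites["site_id"]
    }

    conditions = []
    for cond, n in config.trials_per_condition.items():
        if cond not in CONDITIONS:
            raise ValidationError(f"trials_per_condition: unknown condition {cond!r}")
        conditions += [cond] * int(n)
    conditions = list(p_rng.permutation(conditions))

    ex = config.exclusion_rates
    vd = config.vd_model
    rtm = config.rt_model
    cm = config.choice_model

    event_rows, burst_rows, trial_rows = [], [], []
    t_cursor = config.lead_ms
    for k, cond in enumerate(conditions):
        trial_id = k
        vd1 = float(p_rng.normal(vd.vd1_mean.get(cond, 0.0), vd.vd1_sd))
        vd2 = float(p_rng.normal(0.0, vd.vd2_sd))
        u_t = float(p_rng.normal(0.0, config.shared_duration_sd_ms))

        latest_offset = 0.0
        for _, srow in sites.iterrows():
            sid, roi = srow["site_id"], srow["roi"]
            spec = config.burst_spec.get((roi, cond))
            active = False
            onset = offset = amp = np.nan
            if spec is not None and spec.amplitude > 0:
                if cond == "cognitive" and not srow["cognitive_responsive"]:
                    spec = None
            if spec is not None and spec.amplitude > 0:
                rng_s = site_rngs[sid]
                if rng_s.random() < spec.active_probability:
                    onset = max(rng_s.normal(spec.onset_mean_ms, spec.onset_sd_ms), 20.0)
                    load = config.rt_tracking.get(roi, 0.5)
                    dur = max(
                        rng_s.normal(spec.duration_mean_ms, spec.duration_sd_ms)
                        + load * u_t,
                        100.0,
                    )
                    offset = onset + dur
                    amp = spec.amplitude
                    active = True
                    latest_offset = max(latest_offset, offset)
            burst_rows.append(
                (participant, sid, trial_id, cond, onset, offset, amp, active)
            )

        is_rest = cond == "rest"
        drv_offset = latest_offset if latest_offset > 0 else 1200.0
        rt_latent = (
            rtm.intercept_ms
            + rtm.coupling * drv_offset
            + rtm.b_vd1_ms * vd1
            + p_rng.normal(0.0, rtm.noise_sd_ms)
        )
        rt_latent = max(rt_latent, rtm.floor_ms)
        no_resp = is_rest or (p_rng.random() < ex.get("no_response", 0.0))
        hfo = p_rng.random() < ex.get("hfo", 0.0)
        irrelevant = (not is_rest) and (p_rng.random() < ex.get("irrelevant", 0.0))

        if cond in ("self", "other"):
            trait, valence = _TRAITS[int(p_rng.integers(len(_TRAITS)))]
            val_c = 0.5 if valence == "positive" else -0.5
            type_c = 0.5 if cond == "self" else -0.5
            p_true = float(_sigmoid(cm.b_valence * val_c + cm.b_valence_x_type * val_c * type_c))
            choice = "true" if p_rng.random() < p_true else "false"
        else:
            trait, valence = "", "none"
            p_true = np.nan
            choice = "none" if no_resp else ("true" if p_rng.random() < 0.5 else "false")

        stim_sample = int(round(t_cursor * fs / 1000.0))
        if no_resp:
            response_sample = np.nan
            choice = "none"
            advance = config.timeout_ms
        else:
            response_sample = stim_sample + int(round(rt_latent * fs / 1000.0))
            advance = rt_latent + config.iti_ms
        event_rows.append(
            (trial_id, cond, stim_sample, response_sample, choice, trait, valence,
             vd1, vd2, hfo, irrelevant)
        )
        trial_rows.append((trial_id, drv_offset, rt_latent, p_true))
        t_cursor += advance

    events = pd.DataFrame(
        event_rows,
        columns=["trial_id", "condition", "stim_onset", "response_sample", "choice",
                 "trait", "trait_valence", "vd1", "vd2", "hfo_flag", "irrelevant_press"],
    )
    bursts = pd.DataFrame(
        burst_rows,
        columns=["participant_id", "site_id", "trial_id", "condition",
                 "true_onset_ms", "true_offset_ms", "true_amplitude", "is_active"],
    )
    trials = pd.DataFrame(
        trial_rows, columns=["trial_id", "latest_offset_ms", "rt_latent_ms", "p_true"]
    )
    n_samples = int(round((t_cursor + config.tail_ms) * fs / 1000.0))
    return sites, events, bursts, trials, n_samples


def _synthesize_voltage(
    config: SimulationConfig,
    participant: str,
    sites: pd.DataFrame,
    events: pd.DataFrame,
    bursts: pd.DataFrame,
    n_samples: int,
):
    """Render background + line + calibrated bursts for every channel."""
    fs = config.fs
    stim = events.set_index("trial_id")["stim_onset"]
    voltage = np.empty((len(sites), n_samples), dtype=np.float32)
    calib = []
    t = np.arange(n_samples) / fs
    for ci, sid in enumerate(sites["site_id"]):
        rng_n = _stream(config.seed, participant, sid, "noise")
        bg = pink_noise(n_samples, fs, config.background_exponent, rng_n)
        bg *= config.background_amp_uv
        v_band = _band_variance(bg, fs, *HFB_BAND)
        line = config.line_amp_uv * np.sin(
            2 * np.pi * config.line_freq * t + rng_n.uniform(0, 2 * np.pi)
        )
        x = bg + line

        sb = bursts[(bursts["site_id"] == sid) & bursts["is_active"]]
        k, feasible = _calibration_gain(sb, n_samples, fs, config.ramp_ms)
        # Common-average referencing keeps (1 - 1/n) of a site-specific burst;
        # pre-compensate its power so post-pipeline amplitudes stay on target.
        n_ch = len(sites)
        if n_ch > 1:
            k *= (n_ch / (n_ch - 1.0)) ** 2
        ramp_s = int(round(config.ramp_ms * fs / 1000.0))
        for _, b in sb.iterrows():
            start = int(stim.loc[b["trial_id"]] + round(b["true_onset_ms"] * fs / 1000.0))
            dur_s = max(
                int(round((b["true_offset_ms"] - b["true_onset_ms"]) * fs / 1000.0)), 2
            )
            stop = min(start + dur_s, n_samples)
            if stop <= start:
                continue
            carrier = band_noise(dur_s, fs, *HFB_BAND, config.background_exponent, rng_n)
            env = trapezoid_envelope(dur_s, ramp_s)
            seg = carrier * env * np.sqrt(k * b["true_amplitude"] * v_band)
            x[start:stop] += seg[: stop - start]
        voltage[ci] = x
        calib.append((k, feasible))

    sites = sites.copy()
    sites["calib_k"] = [c[0] for c in calib]
    sites["calib_feasible"] = [c[1] for c in calib]
    return voltage, sites


def simulate_session(
    config: SimulationConfig,
    participant: str = "P01",
    signal: bool = True,
):
    """Simulate one participant session.

    Returns ``(recording, events, ground_truth)``; with ``signal=False`` the
    recording is ``None`` (events and ground truth only), which is useful for
    testing the statistical models without paying for voltage synthesis.
    """
    sites, events_df, bursts, trials, n_samples = _plan_session(config, participant)
    if signal:
        voltage, sites = _synthesize_voltage(
            config, participant, sites, events_df, bursts, n_samples
        )
        channels = [
            ChannelInfo(site_id=s, participant_id=participant, roi=r)
            for s, r in zip(sites["site_id"], sites["roi"])
        ]
        recording = Recording(
            participant_id=participant,
            fs=config.fs,
            channels=channels,
            voltage=voltage,
            line_freq=config.line_freq,
        )
    else:
        recording = None
        sites = sites.copy()
        sites["calib_k"] = np.nan
        sites["calib_feasible"] = True
    sites.insert(0, "participant_id", participant)
    events = EventTable(df=events_df, fs=config.fs)
    truth = GroundTruth(sites=sites, bursts=bursts, trials=trials)
    return recording, events, truth


def simulate_study(config: SimulationConfig, signal: bool = True) -> dict:
    """Simulate all participants; returns {participant_id: (rec, events, truth)}."""
    return {
        f"P{i + 1:02d}": simulate_session(config, f"P{i + 1:02d}", signal=signal)
        for i in range(config.n_participants)
    }


# ---------------------------------------------------------------------------
# deterministic miniature fixtures

FIXTURE_NAMES = (
    "null_no_signal",
    "single_burst",
    "two_roi_lag",
    "specificity_grid",
    "selectivity_grid",
)


def _fixture_config(sites_per_roi, trials, seed, **kw) -> SimulationConfig:
    return SimulationConfig(
        n_participants=1,
        sites_per_roi=sites_per_roi,
        non_roi_sites=kw.pop("non_roi_sites", 16),
        trials_per_condition=trials,
        burst_spec=kw.pop("burst_spec", {("none", "rest"): BurstSpec(0, 0, 100, 0, 0.0, 0.0)}),
        exclusion_rates={"hfo": 0.0, "no_response": 0.0, "irrelevant": 0.0},
        rt_model=kw.pop("rt_model", RTModel(intercept_ms=4000.0, coupling=0.0,
                                            noise_sd_ms=150.0, b_vd1_ms=0.0)),
        shared_duration_sd_ms=kw.pop("shared_duration_sd_ms", 0.0),
        lead_ms=2500.0,
        tail_ms=2500.0,
        seed=seed,
        **kw,
    )


def make_fixture(name: str):
    """Miniature deterministic sessions, each exercising one downstream rule."""
    if name == "null_no_signal":
        cfg = _fixture_config(
            {"TPJ": 2, "PMC": 1}, {"self": 12, "other": 12, "cognitive": 12},
            seed=1101,
        )
        return simulate_session(cfg, "FX")

    if name == "single_burst":
        spec = {
            ("TPJ", "self"): BurstSpec(300.0, 0.0, 400.0, 0.0, 3.0, 1.0),
            ("TPJ", "other"): BurstSpec(300.0, 0.0, 400.0, 0.0, 3.0, 1.0),
        }
        cfg = _fixture_config(
            {"TPJ": 1, "PMC": 1}, {"self": 15, "other": 15, "cognitive": 30},
            seed=1102, burst_spec=spec,
        )
        return simulate_session(cfg, "FX")

    if name == "two_roi_lag":
        spec = {}
        for cond in ("self", "other"):
            spec[("TPJ", cond)] = BurstSpec(300.0, 0.0, 400.0, 0.0, 3.0, 1.0)
            spec[("PMC", cond)] = BurstSpec(450.0, 0.0, 400.0, 0.0, 3.0, 1.0)
        cfg = _fixture_config(
            {"TPJ": 2, "PMC": 2}, {"self": 10, "other": 10, "cognitive": 20},
            seed=1103, burst_spec=spec,
        )
        return simulate_session(cfg, "FX")

    if name == "specificity_grid":
        # Four sites covering (mentalizing-active x cognitive-active) cells:
        # TPJ-00 both, ATL-00 mentalizing only, PMC-00 cognitive only, none.
        spec = {}
        for cond in ("self", "other"):
            spec[("TPJ", cond)] = BurstSpec(300.0, 10.0, 400.0, 20.0, 3.0, 1.0)
            spec[("ATL", cond)] = BurstSpec(300.0, 10.0, 400.0, 20.0, 3.0, 1.0)
        spec[("TPJ", "cognitive")] = BurstSpec(300.0, 10.0, 400.0, 20.0, 3.0, 1.0)
        spec[("PMC", "cognitive")] = BurstSpec(300.0, 10.0, 400.0, 20.0, 3.0, 1.0)
        cfg = _fixture_config(
            {"TPJ": 1, "ATL": 1, "PMC": 1},
            {"self": 12, "other": 12, "cognitive": 12, "episodic": 12},
            seed=1104, burst_spec=spec,
            cognitive_site_p={"TPJ": 1.0, "ATL": 0.0, "PMC": 1.0},
        )
        return simulate_session(cfg, "FX")

    if name == "selectivity_grid":
        # Six sites spanning the selectivity rules: self-greater, other-greater,
        # non-selective, self-only, other-only, inactive.
        spec = {
            ("TPJ", "self"): BurstSpec(300.0, 10.0, 400.0, 20.0, 4.0, 1.0),
            ("TPJ", "other"): BurstSpec(300.0, 10.0, 400.0, 20.0, 2.0, 1.0),
            ("PMC", "self"): BurstSpec(300.0, 10.0, 400.0, 20.0, 2.0, 1.0),
            ("PMC", "other"): BurstSpec(300.0, 10.0, 400.0, 20.0, 4.0, 1.0),
            ("ATL", "self"): BurstSpec(300.0, 10.0, 400.0, 20.0, 3.0, 1.0),
            ("ATL", "other"): BurstSpec(300.0, 10.0, 400.0, 20.0, 3.0, 1.0),
            ("amPFC", "self"): BurstSpec(300.0, 10.0, 400.0, 20.0, 3.0, 1.0),
            ("dmPFC", "other"): BurstSpec(300.0, 10.0, 400.0, 20.0, 3.0, 1.0),
        }
        cfg = _fixture_config(
            {"TPJ": 1, "PMC": 1, "ATL": 1, "amPFC": 1, "dmPFC": 1},
            {"self": 14, "other": 14, "cognitive": 28},
            seed=1105, burst_spec=spec,
        )
        return simulate_session(cfg, "FX")

    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


# ---------------------------------------------------------------------------
# truth-level metrics (detector-free model testing)

def ground_truth_metrics(
    truth: GroundTruth,
    events: EventTable,
    seed: int = 0,
    onset_jitter_ms: float = 8.0,
    power_noise_z: float = 0.3,
) -> pd.DataFrame:
    """Activation-metric table derived from ground truth plus measurement noise.

    Emulates the detector's output for tests of the downstream models without
    running signal synthesis and detection.
    """
    rng = _stream(seed, "truth-metrics")
    m = truth.bursts.merge(
        events.df[["trial_id", "condition", "rt_ms", "choice", "trait",
                   "trait_valence", "vd1", "vd2"]],
        on=["trial_id", "condition"],
        how="inner",
    )
    m = m.merge(truth.sites[["site_id", "roi"]], on="site_id", how="left")
    n = len(m)
    active = m["is_active"].to_numpy(bool)
    onset = m["true_onset_ms"].to_numpy(float) + rng.normal(0, onset_jitter_ms, n)
    offset = m["true_offset_ms"].to_numpy(float) + rng.normal(0, onset_jitter_ms, n)
    dur = offset - onset
    peak = onset + 0.45 * dur + rng.normal(0, onset_jitter_ms, n)
    power = m["true_amplitude"].to_numpy(float) + rng.normal(0, power_noise_z, n)
    out = pd.DataFrame(
        {
            "participant_id": m["participant_id"],
            "site_id": m["site_id"],
            "roi": m["roi"],
            "trial_id": m["trial_id"],
            "condition": m["condition"],
            "rt_ms": m["rt_ms"],
            "choice": m["choice"],
            "vd1": m["vd1"],
            "vd2": m["vd2"],
            "has_activation": active,
            "onset_ms": np.where(active, onset, np.nan),
            "peak_ms": np.where(active, peak, np.nan),
            "offset_ms": np.where(active, offset, np.nan),
            "duration_ms": np.where(active, dur, np.nan),
            "peak_power_z": np.where(
                active, power, np.abs(rng.normal(0.3, power_noise_z, n))
            ),
        }
    )
    return out
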