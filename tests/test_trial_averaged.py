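"""Evoked-timecourse estimation, response labeling, window summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ecogseq.io import ChannelInfo, EventTable
from ecogseq.preprocess import HFBEpochs
from ecogseq.trial_averaged import (
    TimecourseEstimate,
    fit_site_timecourse,
    grand_average_roi,
    label_response,
    time_window_summary,
)

FS = 1000.0


def _epochs(hfb, conditions, rts, rois=None):
    n_sites, n_trials, n_t = hfb.shape
    t_ax = np.arange(-200, n_t - 200) * 1000.0 / FS
    df = pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "condition": conditions,
            "stim_onset": np.arange(n_trials) * (n_t + 500) + 1000,
            "response_sample": np.arange(n_trials) * (n_t + 500)
            + 1000
            + np.asarray(rts, dtype=int),
            "choice": ["true"] * n_trials,
            "trait": [""] * n_trials,
            "trait_valence": ["none"] * n_trials,
            "vd1": np.zeros(n_trials),
            "vd2": np.zeros(n_trials),
            "hfo_flag": [False] * n_trials,
            "irrelevant_press": [False] * n_trials,
        }
    )
    ev = EventTable(df=df, fs=FS)
    rois = rois or ["TPJ"] * n_sites
    valid = np.ones_like(hfb, dtype=bool)
    for i, rt in enumerate(rts):
        valid[:, i, t_ax >= rt + 200] = False
    return HFBEpochs(
        sites=[ChannelInfo(f"s{i}", "P", roi=rois[i]) for i in range(n_sites)],
        trials=ev.df,
        hfb=hfb.astype(np.float32),
        time_axis=t_ax,
        valid_mask=valid,
        fs=FS,
    )


def test_beta_equals_mixed_model_oracle():
    """The per-timepoint estimate must equal an explicit per-trial
    random-intercept LMEM with baseline pool and one timepoint dummy."""
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(0)
    n_trials, n_t = 10, 400
    hfb = rng.normal(0, 1, (1, n_trials, n_t))
    hfb[0, :, 250:] += 1.0
    ep = _epochs(hfb, ["self"] * n_trials, [900.0] * n_trials)
    # baseline-correct as the pipeline guarantees
    bsel = (ep.time_axis >= -200) & (ep.time_axis < 0)
    ep.hfb -= ep.hfb[:, :, bsel].mean(axis=2, keepdims=True)
    est = fit_site_timecourse(ep, "s0", "self")
    for t_idx in [30, 120, 180]:
        t_ms = est.time_axis[t_idx]
        rows = []
        for i in range(n_trials):
            for b in np.flatnonzero(bsel):
                rows.append(dict(trial=i, dummy=0.0, y=float(ep.hfb[0, i, b])))
            j = np.flatnonzero(ep.time_axis == t_ms)[0]
            rows.append(dict(trial=i, dummy=1.0, y=float(ep.hfb[0, i, j])))
        df = pd.DataFrame(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm("y ~ dummy", df, groups=df["trial"]).fit(reml=True)
        assert est.beta[t_idx] == pytest.approx(fit.params["dummy"], abs=1e-6)


def test_trial_order_permutation_leaves_beta_unchanged():
    rng = np.random.default_rng(1)
    hfb = rng.normal(0, 1, (1, 12, 400))
    ep = _epochs(hfb, ["self"] * 12, [900.0] * 12)
    est1 = fit_site_timecourse(ep, "s0", "self")
    perm = rng.permutation(12)
    ep2 = _epochs(hfb[:, perm], ["self"] * 12, [900.0] * 12)
    est2 = fit_site_timecourse(ep2, "s0", "self")
    assert np.allclose(
        np.nan_to_num(est1.beta), np.nan_to_num(est2.beta), atol=1e-6
    )


def test_too_few_trials_skipped_with_warning():
    hfb = np.zeros((1, 3, 400))
    ep = _epochs(hfb, ["self"] * 3, [900.0] * 3)
    with pytest.warns(UserWarning, match="skipped"):
        assert fit_site_timecourse(ep, "s0", "self") is None


class TestLabeling:
    def _estimate(self, beta, sig):
        return TimecourseEstimate(
            site_id="s", condition="self", time_axis=np.arange(len(beta), dtype=float),
            beta=np.asarray(beta, dtype=float), se=np.ones(len(beta)),
            p=np.ones(len(beta)), sig=np.asarray(sig, dtype=bool),
        )

    @pytest.mark.parametrize(
        "beta, sig, expected",
        [
            ([1, 2, 1], [1, 1, 0], "active"),
            ([-1, -2, 0], [1, 1, 0], "deactive"),
            ([1, -3, 1], [1, 1, 1], "deactive"),  # greatest deflection negative
            ([3, -1, 1], [1, 1, 0], "active"),  # greatest deflection positive
            ([1, 2, 3], [0, 0, 0], "nonresponsive"),
        ],
    )
    def test_truth_table(self, beta, sig, expected):
        assert label_response(self._estimate(beta, sig)) == expected

    def test_none_estimate_is_nonresponsive(self):
        assert label_response(None) == "nonresponsive"


def test_null_sites_rarely_labeled_responsive(null_run):
    labels = null_run["labels"]
    ment = labels[labels.condition == "mentalizing"]
    assert (ment["label"] != "nonresponsive").mean() < 0.05


class TestWindowSummary:
    def test_confined_burst_hits_right_window(self):
        rng = np.random.default_rng(2)
        hfb = rng.normal(0, 0.3, (1, 12, 2400))
        t_ax = np.arange(-200, 2200)
        hfb[0, :, (t_ax >= 300) & (t_ax < 500)] += 2.0
        ep = _epochs(hfb, ["self"] * 12, [1900.0] * 12)
        df = time_window_summary(ep, conditions=["self"])
        row = df[(df.window_start_ms == 250) & (df.window_end_ms == 500)].iloc[0]
        far = df[(df.window_start_ms == 1000)].iloc[0]
        assert row["sig"] and row["t"] > 0
        assert not far["sig"]

    def test_window_beyond_epoch_rejected(self):
        hfb = np.zeros((1, 12, 1200))
        ep = _epochs(hfb, ["self"] * 12, [700.0] * 12)
        with pytest.raises(ValueError, match="epoch"):
            time_window_summary(ep, windows=[(0, 5000)], conditions=["self"])

    def test_fully_masked_window_flagged_untested(self):
        rng = np.random.default_rng(3)
        hfb = rng.normal(size=(1, 12, 2400))
        ep = _epochs(hfb, ["self"] * 12, [500.0] * 12)  # valid ends at 700 ms
        df = time_window_summary(ep, conditions=["self"])
        far = df[df.window_start_ms == 1000].iloc[0]
        assert not far["tested"]


class TestGrandAverage:
    def _fit(self, ep, site):
        est = fit_site_timecourse(ep, site, "self")
        est.sig = np.zeros(est.beta.size, dtype=bool)
        return est

    def test_single_site_passthrough(self):
        rng = np.random.default_rng(4)
        hfb = rng.normal(size=(1, 10, 2400))
        ep = _epochs(hfb, ["self"] * 10, [1900.0] * 10)
        est = self._fit(ep, "s0")
        ga = grand_average_roi([est], "TPJ", "self")
        n = ga.beta.size
        assert np.allclose(np.nan_to_num(ga.beta), np.nan_to_num(est.beta[:n]))

    def test_identical_sites_shrink_se(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(1, 10, 2400))
        hfb = np.concatenate([base, base], axis=0)
        ep = _epochs(hfb, ["self"] * 10, [1900.0] * 10, rois=["TPJ", "TPJ"])
        e1, e2 = self._fit(ep, "s0"), self._fit(ep, "s1")
        ga = grand_average_roi([e1, e2], "TPJ", "self")
        assert np.allclose(np.nan_to_num(ga.beta), np.nan_to_num(e1.beta[: ga.beta.size]))
        finite = np.isfinite(ga.se) & np.isfinite(e1.se[: ga.se.size])
        assert np.all(ga.se[finite] <= e1.se[: ga.se.size][finite] + 1e-12)

    def test_empty_roi_returns_none(self):
        assert grand_average_roi([], "TPJ", "self") is None


def test_roi_grand_average_onset_ordering(single_burst_run, two_roi_run):
    # earlier-onset ROI crosses half its plateau before the later one
    ests = [
        e for e in two_roi_run["estimates"].values() if e.condition == "mentalizing"
    ]
    ga_a = grand_average_roi(ests, "TPJ", "mentalizing")
    ga_b = grand_average_roi(ests, "PMC", "mentalizing")
    def crossing(ga):
        half = np.nanmax(ga.beta) / 2
        return ga.time_axis[np.argmax(ga.beta >= half)]
    assert crossing(ga_a) < crossing(ga_b)
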