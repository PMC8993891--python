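"""ROI-level mixed models: outlier rules, pairwise contrasts, second-level fits."""

import warnings

import numpy as np
import pandas as pd
import pytest

from ecogseq import roi as R
from ecogseq.simulate import (
    ROI_ONSET_MS,
    SimulationConfig,
    ground_truth_metrics,
    simulate_session,
)


@pytest.fixture(scope="module")
def truth_metrics():
    """Detector-free metrics from 4 participants, 2 sites per ROI."""
    cfg = SimulationConfig(
        n_participants=4,
        sites_per_roi={r: 2 for r in ROI_ONSET_MS},
        non_roi_sites=0,
        trials_per_condition={"self": 25, "other": 25, "cognitive": 15},
        seed=7,
    )
    frames = []
    for i in range(4):
        _, ev, truth = simulate_session(cfg, f"P{i + 1:02d}", signal=False)
        frames.append(ground_truth_metrics(truth, ev, seed=100 + i))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="module")
def active_sites(truth_metrics):
    return sorted(truth_metrics["site_id"].unique())


class TestOutlierFilter:
    def test_clean_data_barely_touched(self, truth_metrics, active_sites):
        filtered, excluded, summary = R.multisite_outlier_filter(
            truth_metrics, active_sites
        )
        assert excluded == []
        dropped = summary["n_flagged"].sum() / summary["n_obs"].sum()
        # two 3-scaled-MAD passes over five heavy-tailed metrics flag ~2.5%
        # of clean observations (own Monte-Carlo); sites must never trip the
        # 50% exclusion rule on clean data
        assert dropped < 0.04

    def test_corrupt_site_excluded(self, truth_metrics, active_sites):
        rng = np.random.default_rng(0)
        bad = truth_metrics.copy()
        sel = bad["site_id"] == "P01-TPJ-00"
        # replace this site's metrics with noise far outside the ROI pool
        n = sel.sum()
        for col, lo, hi in [("onset_ms", 3000, 4500), ("peak_ms", 3000, 4800),
                            ("offset_ms", 4000, 4900), ("duration_ms", 2500, 4000)]:
            bad.loc[sel, col] = rng.uniform(lo, hi, n)
        filtered, excluded, _ = R.multisite_outlier_filter(bad, active_sites)
        assert "P01-TPJ-00" in excluded
        assert "P01-TPJ-00" not in filtered["site_id"].values

    def test_rt_over_5000_excluded_first(self, truth_metrics, active_sites):
        m = truth_metrics.copy()
        m.loc[m.index[:5], "rt_ms"] = 6000.0
        filtered, _, _ = R.multisite_outlier_filter(m, active_sites)
        assert (filtered["rt_ms"] <= 5000).all()

    def test_empty_input(self):
        empty = pd.DataFrame(
            columns=["participant_id", "site_id", "roi", "trial_id", "condition",
                     "rt_ms", "choice", "vd1", "vd2", "has_activation",
                     *R.METRIC_COLUMNS]
        )
        filtered, excluded, _ = R.multisite_outlier_filter(empty, [])
        assert filtered.empty and excluded == []

    def test_mahalanobis_switch_runs(self, truth_metrics, active_sites):
        filtered, excluded, _ = R.multisite_outlier_filter(
            truth_metrics, active_sites, method="mahalanobis"
        )
        assert excluded == []


class TestTypeRtChoiceModels:
    def test_other_duration_effect_recovered(self):
        # RT decoupled from condition so the RT-controlled Type estimand
        # equals the generator's direct +150 ms duration increment
        from ecogseq.simulate import RTModel

        cfg = SimulationConfig(
            n_participants=3,
            sites_per_roi={"dmPFC": 2},
            non_roi_sites=0,
            trials_per_condition={"self": 30, "other": 30},
            rt_model=RTModel(intercept_ms=2500.0, coupling=0.0,
                             noise_sd_ms=400.0, b_vd1_ms=0.0),
            shared_duration_sd_ms=0.0,
            seed=21,
        )
        frames = []
        for i in range(3):
            _, ev, truth = simulate_session(cfg, f"P{i + 1:02d}", signal=False)
            frames.append(ground_truth_metrics(truth, ev, seed=300 + i))
        m = pd.concat(frames, ignore_index=True)
        res = R.fit_roi_type_rt_choice(m, "dmPFC", "duration_ms")
        e = res.effects["Type_Other-Self"]
        assert abs(e.b - 150.0) < 3 * e.se
        assert e.p < 0.01

    def test_type_invariant_metric_nonsignificant(self, truth_metrics):
        res = R.fit_roi_type_rt_choice(truth_metrics, "dmPFC", "onset_ms")
        e = res.effects["Type_Other-Self"]
        assert abs(e.b) < 3 * e.se + 10  # onsets do not differ by type

    def test_offset_tracks_rt_along_hierarchy(self, truth_metrics):
        slopes = {}
        for roi in ("Visual", "vmPFC"):
            res = R.fit_roi_type_rt_choice(truth_metrics, roi, "offset_ms")
            slopes[roi] = res.effects["RT_Behav"].b
        assert slopes["vmPFC"] > slopes["Visual"] + 0.3

    def test_tiny_roi_returns_none(self, truth_metrics):
        assert R.fit_roi_type_rt_choice(truth_metrics.head(5), "TPJ", "onset_ms") is None


class TestPairwise:
    def test_self_comparison_is_zero(self, truth_metrics):
        est = R.pairwise_roi_latency(truth_metrics, "TPJ", "TPJ")
        assert est.b == 0.0

    def test_antisymmetry_exact(self, truth_metrics):
        a = R.pairwise_roi_latency(truth_metrics, "Visual", "vmPFC")
        b = R.pairwise_roi_latency(truth_metrics, "vmPFC", "Visual")
        assert a.b == pytest.approx(-b.b, rel=1e-6)

    def test_missing_overlap_not_estimable(self, truth_metrics):
        m = truth_metrics[truth_metrics["roi"] != "vmPFC"]
        assert R.pairwise_roi_latency(m, "TPJ", "vmPFC") is None

    def test_two_roi_lag_recovered_through_detector(self, two_roi_run):
        est = R.pairwise_roi_latency(
            two_roi_run["metrics"], "PMC", "TPJ", "onset_ms"
        )
        assert 130 <= est.b <= 170  # constructed 150-ms lag

    def test_matrix_ordering_matches_generator(self, truth_metrics):
        df = R.pairwise_roi_matrix(truth_metrics, list(ROI_ONSET_MS), "onset_ms")
        for _, row in df.iterrows():
            true_diff = ROI_ONSET_MS[row.roi_x] - ROI_ONSET_MS[row.roi_y]
            if abs(true_diff) > 30:
                assert np.sign(row.b) == np.sign(true_diff), (row.roi_x, row.roi_y)


class TestSecondLevel:
    def test_onset_predicts_specificity_slope_recovered(self):
        # generator: P(specific) = logistic(0.014 * (onset - 400 ms))
        rng = np.random.default_rng(42)
        n = 255
        onsets = rng.uniform(80, 600, n)
        p = 1 / (1 + np.exp(-0.014 * (onsets - 400.0)))
        df = pd.DataFrame(
            {
                "participant_id": rng.choice([f"P{i}" for i in range(8)], n),
                "mean_onset_ms": onsets,
                "specific": rng.random(n) < p,
            }
        )
        est = R.onset_predicts_specificity(df)
        assert abs(est.b - 0.014) < 2 * est.se
        assert est.or_value == pytest.approx(np.exp(est.b), rel=1e-12)

    def test_shuffled_labels_give_or_near_one(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "participant_id": rng.choice(["P1", "P2", "P3"], 200),
                "mean_onset_ms": rng.uniform(80, 600, 200),
                "specific": rng.random(200) < 0.5,
            }
        )
        est = R.onset_predicts_specificity(df)
        assert abs(est.b) < 2.5 * est.se

    def test_single_class_exercises_separation_path(self):
        df = pd.DataFrame(
            {
                "participant_id": ["P1"] * 20,
                "mean_onset_ms": np.linspace(100, 500, 20),
                "specific": [True] * 20,
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = R.onset_predicts_specificity(df)
        assert "penalized" in est.method or "glm" in est.method

    def test_onset_vs_effect_size_recovery(self):
        rng = np.random.default_rng(4)
        n = 60
        onsets = rng.uniform(100, 550, n)
        slope = 0.0006
        eff = slope * onsets + rng.normal(0, 0.02, n)
        df = pd.DataFrame(
            {
                "participant_id": rng.choice(["P1", "P2", "P3", "P4"], n),
                "mean_onset_ms": onsets,
                "rt_slope": eff,
            }
        )
        est = R.onset_vs_effect_size(df)
        assert abs(est.b - slope) < 3 * est.se

    def test_too_few_sites_raises(self):
        df = pd.DataFrame(
            {"participant_id": ["P"] * 5, "mean_onset_ms": range(5),
             "rt_slope": range(5)}
        )
        with pytest.raises(ValueError):
            R.onset_vs_effect_size(df)

    def test_site_rt_effects_rise_with_onset(self, truth_metrics):
        se_tab = R.site_rt_effects(truth_metrics, "peak_ms")
        est = R.onset_vs_effect_size(se_tab, "rt_slope")
        assert est.b > 0
        assert est.p < 0.01


class TestMpfcOffset:
    def test_generator_gap_recovered(self, truth_metrics):
        est = R.mpfc_offset_vs_rt(truth_metrics)
        # generator offsets: mPFC bursts end later, hence closer to RT
        gaps = truth_metrics.dropna(subset=["offset_ms"])
        gaps = gaps[gaps["condition"].isin(["self", "other"])]
        true_gap = (
            (gaps.loc[~gaps.roi.isin(("amPFC", "dmPFC", "vmPFC")), "rt_ms"]
             - gaps.loc[~gaps.roi.isin(("amPFC", "dmPFC", "vmPFC")), "offset_ms"]).mean()
            - (gaps.loc[gaps.roi.isin(("amPFC", "dmPFC", "vmPFC")), "rt_ms"]
               - gaps.loc[gaps.roi.isin(("amPFC", "dmPFC", "vmPFC")), "offset_ms"]).mean()
        )
        assert est.b == pytest.approx(true_gap, abs=4 * est.se + 20)
        assert est.b > 0

    def test_no_mpfc_sites_raises(self, truth_metrics):
        m = truth_metrics[~truth_metrics["roi"].isin(("amPFC", "dmPFC", "vmPFC"))]
        with pytest.raises(ValueError):
            R.mpfc_offset_vs_rt(m)
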