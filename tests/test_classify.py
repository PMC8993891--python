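"""Specificity/selectivity decision rules and peak-power comparisons."""

import numpy as np
import pandas as pd
import pytest

from ecogseq.classify import (
    SiteProfile,
    classify_selectivity,
    classify_sites,
    classify_specificity,
    compare_peak_power,
    selectivity_counts,
)
from ecogseq.io import EffectEstimate


def _cmp(b, sig):
    est = EffectEstimate(name="peak_power_diff", b=b, se=0.1, p=0.01 if sig else 0.5,
                         df=20.0)
    return est, sig


def _profile(mz, cog=False, self_a=False, other_a=False,
             mz_cog=(0.0, False), self_other=(0.0, False)):
    p = SiteProfile(site_id="s", mentalizing_active=mz, cognitive_active=cog,
                    self_active=self_a, other_active=other_a)
    p.mz_vs_cog, p.mz_vs_cog_sig = _cmp(*mz_cog)
    p.self_vs_other, p.self_vs_other_sig = _cmp(*self_other)
    return p


class TestSpecificityRules:
    @pytest.mark.parametrize(
        "mz, cog, cmp_b, cmp_sig, expected",
        [
            # coactivation wins regardless of power difference
            (True, True, 5.0, True, "non_specific"),
            (True, False, 1.0, True, "mentalizing_specific"),
            (True, False, 1.0, False, "non_specific"),
            (True, False, -1.0, True, "non_specific"),  # excess must favor mentalizing
            (False, True, 1.0, True, "not_applicable"),
            (False, False, 0.0, False, "not_applicable"),
        ],
    )
    def test_truth_table(self, mz, cog, cmp_b, cmp_sig, expected):
        p = _profile(mz, cog=cog, mz_cog=(cmp_b, cmp_sig))
        assert classify_specificity(p) == expected


class TestSelectivityRules:
    @pytest.mark.parametrize(
        "self_a, other_a, d, sig, expected",
        [
            (True, True, 1.0, True, "self_greater"),
            (True, True, -1.0, True, "other_greater"),
            (True, True, 0.5, False, "non_selective"),
            (True, False, 1.0, True, "self_only"),
            (True, False, 1.0, False, "non_selective"),
            (False, True, -1.0, True, "other_only"),
            (False, True, 1.0, True, "non_selective"),  # wrong-direction excess
            (False, False, 0.0, False, "non_selective"),
        ],
    )
    def test_truth_table_mentalizing_active(self, self_a, other_a, d, sig, expected):
        p = _profile(True, self_a=self_a, other_a=other_a, self_other=(d, sig))
        assert classify_selectivity(p) == expected

    def test_inactive_site_not_applicable(self):
        assert classify_selectivity(_profile(False)) == "not_applicable"

    def test_rules_are_total(self):
        # every (activity x comparison) combination yields exactly one label
        for self_a in (False, True):
            for other_a in (False, True):
                for d in (-1.0, 0.0, 1.0):
                    for sig in (False, True):
                        p = _profile(True, self_a=self_a, other_a=other_a,
                                     self_other=(d, sig), mz_cog=(d, sig))
                        assert classify_selectivity(p) in (
                            "self_only", "other_only", "self_greater",
                            "other_greater", "non_selective")
                        assert classify_specificity(p) in (
                            "mentalizing_specific", "non_specific")


def _metrics(site, powers_by_cond):
    rows = []
    for cond, powers in powers_by_cond.items():
        for i, pw in enumerate(powers):
            rows.append(dict(participant_id="P", site_id=site, roi="TPJ",
                             trial_id=len(rows), condition=cond, rt_ms=1500.0,
                             choice="true", vd1=0.0, vd2=0.0,
                             has_activation=True, peak_power_z=pw))
    return pd.DataFrame(rows)


class TestPeakPowerComparison:
    def test_identical_distributions_nonsignificant(self):
        rng = np.random.default_rng(0)
        m = _metrics("s", {"self": rng.normal(2, 0.3, 15),
                           "other": rng.normal(2, 0.3, 15)})
        est = compare_peak_power(m, "s", ["self"], ["other"])
        assert abs(est.b) < 0.3
        assert est.p > 0.05

    def test_unit_shift_recovered(self):
        rng = np.random.default_rng(1)
        m = _metrics("s", {"self": rng.normal(3, 0.3, 20),
                           "other": rng.normal(2, 0.3, 20)})
        est = compare_peak_power(m, "s", ["self"], ["other"])
        assert 0.8 <= est.b <= 1.2
        assert est.p < 0.01

    def test_gross_outlier_does_not_flip_sign(self):
        rng = np.random.default_rng(2)
        a = rng.normal(3, 0.3, 20)
        b = rng.normal(2, 0.3, 20)
        b[0] = 40.0  # contamination
        m = _metrics("s", {"self": a, "other": b})
        est = compare_peak_power(m, "s", ["self"], ["other"])
        assert est.b > 0

    def test_insufficient_trials_returns_none(self):
        m = _metrics("s", {"self": [1, 2, 3], "other": np.ones(10)})
        assert compare_peak_power(m, "s", ["self"], ["other"]) is None


class TestSelectivityCounts:
    def _profiles(self, labels):
        out = []
        for i, lab in enumerate(labels):
            p = SiteProfile(site_id=f"s{i}", roi="TPJ", mentalizing_active=True)
            p.selectivity = lab
            out.append(p)
        return out

    def test_all_non_selective(self):
        n_self, n_other, test = selectivity_counts(self._profiles(["non_selective"] * 5))
        assert (n_self, n_other) == (0, 0)
        assert test.statistic == 0.0

    def test_2_vs_10_gives_chi2_49_12(self):
        labels = ["self_only", "self_greater"] + ["other_greater"] * 10
        n_self, n_other, test = selectivity_counts(self._profiles(labels))
        assert (n_self, n_other) == (2, 10)
        assert test.statistic == pytest.approx(49 / 12)

    def test_swap_symmetry(self):
        labels = ["self_only"] * 3 + ["other_greater"] * 7
        swapped = ["other_only"] * 3 + ["self_greater"] * 7
        _, _, t1 = selectivity_counts(self._profiles(labels))
        _, _, t2 = selectivity_counts(self._profiles(swapped))
        assert t1.statistic == t2.statistic

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError):
            selectivity_counts([], "vmPFC")


class TestGridFixtures:
    def test_specificity_grid_cells(self, specificity_run):
        profiles = classify_sites(
            specificity_run["metrics"], specificity_run["labels"]
        )
        by_site = {p.site_id.split("-", 1)[1]: p for p in profiles}
        assert by_site["TPJ-00"].specificity == "non_specific"  # mz + cog
        assert by_site["ATL-00"].specificity == "mentalizing_specific"  # mz only
        assert by_site["PMC-00"].specificity == "not_applicable"  # cog only
        assert by_site["PMC-00"].cognitive_active
        assert by_site["X-00"].specificity == "not_applicable"  # silent

    def test_selectivity_grid_cells(self, selectivity_run):
        profiles = classify_sites(
            selectivity_run["metrics"], selectivity_run["labels"]
        )
        by_site = {p.site_id.split("-", 1)[1]: p for p in profiles}
        assert by_site["TPJ-00"].selectivity == "self_greater"
        assert by_site["PMC-00"].selectivity == "other_greater"
        assert by_site["ATL-00"].selectivity == "non_selective"
        assert by_site["amPFC-00"].selectivity == "self_only"
        assert by_site["dmPFC-00"].selectivity == "other_only"
        assert by_site["X-00"].selectivity == "not_applicable"
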