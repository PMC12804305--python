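"""%ID/g, SUV, contrast-ratio and group-summary computations."""

import copy
import math
from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from biodist import (CalibrationResult, CountingSample, InjectionRecord,
                     SyringeRecord, analyze_study, contrast_ratios,
                     group_summary, injected_activity, net_cpm,
                     pct_id_per_gram, suv)

T0 = datetime(2026, 1, 5, 8, 0, 0)
T_REF = datetime(2026, 1, 5, 14, 0, 0)


def _cf(cf_mass=5.0e6, cf_activity=None):
    return CalibrationResult(cf_mass=cf_mass, per_standard_cf=[cf_mass] * 4,
                             cv=0.0, background_cpm=30.0,
                             standard_mass_delivered=0.1042,
                             stock_total_mass=10.1042,
                             cf_activity=cf_activity)


def _syringe(full=2.6242, empty=2.5000, role="animal"):
    return SyringeRecord(syringe_id="S01", role=role, mass_full=full,
                         t_weigh_full=T0, mass_empty=empty, t_weigh_empty=T0)


class TestInjectedActivity:
    def test_mass_route(self):
        dose = injected_activity(_syringe(), _cf())
        assert dose.injected_mass == pytest.approx(0.1242)
        assert dose.injected_cpm == pytest.approx(6.21e5, rel=1e-9)

    def test_zero_injected_mass_is_an_error(self):
        with pytest.raises(ValueError):
            injected_activity(_syringe(full=2.5, empty=2.5), _cf())

    def test_override_uses_cpm_per_mbq_factor(self):
        dose = injected_activity(_syringe(), _cf(cf_activity=2.605e5),
                                 override_mbq=1.5)
        assert dose.injected_cpm == pytest.approx(3.9075e5, rel=1e-9)
        assert dose.override_used

    def test_override_without_activity_factor_is_an_error(self):
        with pytest.raises(ValueError, match="CPM/MBq"):
            injected_activity(_syringe(), _cf(), override_mbq=1.5)

    def test_standard_syringe_rejected(self):
        with pytest.raises(ValueError):
            injected_activity(_syringe(role="standard"), _cf())


def _tissue(cpm, full=2.1, empty=2.0):
    return CountingSample(tube_id="T1", role="tissue", tube_empty_mass=empty,
                          tube_full_mass=full, cpm=cpm, t_count_ref=T_REF,
                          animal_id="A1", tissue_name="blood")


class TestNetCpm:
    def test_subtracts_background(self):
        assert net_cpm(_tissue(1030.0), 30.0) == (1000.0, [])

    def test_equal_to_background_gives_zero(self):
        assert net_cpm(_tissue(30.0), 30.0) == (0.0, [])

    def test_flag_policy_keeps_negative_value(self):
        value, flags = net_cpm(_tissue(10.0), 30.0, policy="flag")
        assert value == -20.0
        assert flags == ["negative_net"]

    def test_clamp_policy_zeroes_but_still_flags(self):
        value, flags = net_cpm(_tissue(10.0), 30.0, policy="clamp")
        assert value == 0.0
        assert flags == ["negative_net"]


class TestPctIdAndSuv:
    def test_worked_example(self):
        assert pct_id_per_gram(12420.0, 0.100, 6.21e5) == pytest.approx(20.0)

    def test_zero_net_gives_zero(self):
        assert pct_id_per_gram(0.0, 0.1, 6.21e5) == 0.0

    def test_whole_carcass_conservation(self):
        # the whole injected activity in a 1 g sample is 100 %ID/g
        assert pct_id_per_gram(6.21e5, 1.0, 6.21e5) == pytest.approx(100.0)

    def test_zero_mass_is_reported_missing_not_zero(self):
        with pytest.raises(ValueError):
            pct_id_per_gram(100.0, 0.0, 6.21e5)

    def test_suv_by_body_weight(self):
        assert suv(20.0, 20.0) == pytest.approx(4.0)

    def test_uniform_distribution_fixed_point(self):
        bw = 23.7
        assert suv(100.0 / bw, bw) == pytest.approx(1.0)

    def test_zero_uptake_gives_zero_suv(self):
        assert suv(0.0, 25.0) == 0.0


def _results_frame(rows):
    return pd.DataFrame(rows, columns=["animal_id", "tissue_name",
                                       "pct_id_per_g"])


def _inj(animal, group="g1", excluded=False):
    return InjectionRecord(animal_id=animal, syringe_id="S01", group=group,
                           t_injection=T0, body_weight=20.0,
                           exclusion_flag=excluded)


class TestContrastRatios:
    def test_tumor_to_muscle_ratio(self):
        per, grp = contrast_ratios(
            _results_frame([("A1", "tumor", 20.0), ("A1", "muscle", 2.0)]),
            [_inj("A1")], targets=["tumor"], backgrounds=["muscle"])
        assert per.ratio.iloc[0] == pytest.approx(10.0)
        assert grp["mean"].iloc[0] == pytest.approx(10.0)

    def test_equal_uptake_gives_unity(self):
        per, _ = contrast_ratios(
            _results_frame([("A1", "tumor", 5.0), ("A1", "muscle", 5.0)]),
            [_inj("A1")], targets=["tumor"], backgrounds=["muscle"])
        assert per.ratio.iloc[0] == pytest.approx(1.0)

    def test_zero_background_is_flagged_undefined(self):
        per, grp = contrast_ratios(
            _results_frame([("A1", "tumor", 20.0), ("A1", "muscle", 0.0)]),
            [_inj("A1")], targets=["tumor"], backgrounds=["muscle"])
        assert math.isnan(per.ratio.iloc[0])
        assert per.flag.iloc[0] == "nonpositive_background"

    def test_ratio_is_per_animal_then_averaged(self):
        # pairing matters: mean of (20/2, 10/5) != mean(20,10)/mean(2,5)
        per, grp = contrast_ratios(
            _results_frame([("A1", "tumor", 20.0), ("A1", "muscle", 2.0),
                            ("A2", "tumor", 10.0), ("A2", "muscle", 5.0)]),
            [_inj("A1"), _inj("A2")], targets=["tumor"],
            backgrounds=["muscle"])
        assert grp["mean"].iloc[0] == pytest.approx((10.0 + 2.0) / 2)


def _summary_frame(values, tissue="liver"):
    rows = [{"animal_id": f"A{i}", "tissue_name": tissue, "pct_id_per_g": v,
             "pct_id_organ": v, "suv": v / 5.0} for i, v in enumerate(values)]
    return pd.DataFrame(rows)


class TestGroupSummary:
    def test_mean_sd_cv_with_sample_denominator(self):
        out = group_summary(_summary_frame([1.0, 2.0, 3.0]),
                            [_inj("A0"), _inj("A1"), _inj("A2")])
        row = out.iloc[0]
        assert row["n"] == 3
        assert row["pct_id_per_g_mean"] == pytest.approx(2.0)
        assert row["pct_id_per_g_sd"] == pytest.approx(1.0)
        assert row["pct_id_per_g_cv"] == pytest.approx(50.0)

    def test_single_animal_has_undefined_sd_and_flag(self):
        out = group_summary(_summary_frame([2.0]), [_inj("A0")])
        assert out.iloc[0]["n"] == 1
        assert math.isnan(out.iloc[0]["pct_id_per_g_sd"])
        assert out.iloc[0]["flag"] == "n=1"

    def test_excluded_animals_are_omitted(self):
        out = group_summary(
            _summary_frame([1.0, 2.0, 100.0]),
            [_inj("A0"), _inj("A1"), _inj("A2", excluded=True)])
        assert out.iloc[0]["n"] == 2
        assert out.iloc[0]["pct_id_per_g_mean"] == pytest.approx(1.5)

    def test_all_excluded_is_an_error(self):
        with pytest.raises(ValueError):
            group_summary(_summary_frame([1.0]), [_inj("A0", excluded=True)])


# ---------------------------------------------------------------------------
# end-to-end properties on the synthetic study


def test_zero_noise_study_recovers_truth_everywhere(clean_results):
    results, truth = clean_results
    for _, row in results.per_animal.iterrows():
        t = truth.animals[row.animal_id]["tissues"][row.tissue_name]
        assert row.pct_id_per_g == pytest.approx(t["pct_id_per_g"], rel=1e-9)
        assert row.suv == pytest.approx(t["suv"], rel=1e-9)
    for _, row in results.injected.iterrows():
        t = truth.animals[row.animal_id]
        assert row.injected_cpm == pytest.approx(t["injected_cpm"], rel=1e-9)


def test_mass_and_calibrator_injected_activity_agree_on_clean_data(
        clean_results):
    results, truth = clean_results
    for _, row in results.injected.iterrows():
        t = truth.animals[row.animal_id]
        assert row.injected_MBq_calibrator == pytest.approx(
            t["injected_MBq"], rel=1e-9)
        assert abs(row.mass_vs_calibrator_rel_diff) < 1e-9


def test_pct_id_organ_equals_concentration_times_mass(clean_results):
    results, _ = clean_results
    for _, row in results.per_animal.iterrows():
        assert row.pct_id_organ == pytest.approx(
            row.pct_id_per_g * row.mass_g, rel=1e-12)


def test_rescaling_every_cpm_leaves_results_invariant(clean_study):
    bundle, _ = clean_study
    base = analyze_study(bundle)
    scaled_bundle = copy.deepcopy(bundle)
    for s in scaled_bundle.samples:
        s.cpm *= 17.0
    scaled = analyze_study(scaled_bundle)
    assert np.allclose(scaled.per_animal["pct_id_per_g"],
                       base.per_animal["pct_id_per_g"], rtol=1e-12)
    assert np.allclose(scaled.per_animal["suv"], base.per_animal["suv"],
                       rtol=1e-12)
    assert np.allclose(scaled.ratios["mean"], base.ratios["mean"], rtol=1e-12)
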