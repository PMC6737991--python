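"""Target-yield rule, N/P/K rate rules and split scheduling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricessnm import (
    EngineConfig,
    FarmerInterview,
    SchedulingError,
    build_prescription,
    k_rate,
    k_split_amounts,
    n_rate,
    n_split_amounts,
    p_rate,
    set_target_yield,
    stage_schedule,
)


def make_interview(**overrides):
    base = dict(
        field_id="X",
        growth_duration_days=135,
        seedling_age_days=25,
        historical_yield_GYR=4.5,
    )
    base.update(overrides)
    return FarmerInterview(**base)


class TestTargetYield:
    @pytest.mark.parametrize(
        "gyr, expected",
        [(4.6, 5.1), (3.7, 4.2), (2.0, 3.0), (6.4, 6.5), (0.5, 3.0), (9.0, 6.5)],
    )
    def test_uplift_and_clamping(self, cfg, gyr, expected):
        iv = make_interview(historical_yield_GYR=gyr)
        assert set_target_yield(iv, cfg) == pytest.approx(expected)

    def test_variety_ceiling_caps_before_clamping(self, cfg):
        iv = make_interview(historical_yield_GYR=4.6, variety_yield_ceiling=4.8)
        assert set_target_yield(iv, cfg) == pytest.approx(4.8)

    def test_late_transplanting_lowers_target(self, cfg):
        on_time = make_interview(historical_yield_GYR=4.6)
        late = make_interview(historical_yield_GYR=4.6, transplant_delay_days=14)
        assert set_target_yield(late, cfg) == pytest.approx(
            set_target_yield(on_time, cfg) - 2 * cfg.late_penalty_per_week
        )

    def test_nonpositive_history_rejected(self):
        with pytest.raises(ValueError):
            make_interview(historical_yield_GYR=0.0)

    @given(
        gyr=st.floats(0.5, 10.0),
        delay=st.floats(0, 60),
    )
    @settings(max_examples=200, deadline=None)
    def test_always_within_bounds_and_monotone(self, gyr, delay):
        cfg = EngineConfig()
        ty = set_target_yield(make_interview(historical_yield_GYR=gyr,
                                             transplant_delay_days=delay), cfg)
        assert cfg.ty_min <= ty <= cfg.ty_max
        # monotone non-decreasing in history, non-increasing in delay
        ty_up = set_target_yield(
            make_interview(historical_yield_GYR=gyr + 0.5, transplant_delay_days=delay), cfg
        )
        ty_later = set_target_yield(
            make_interview(historical_yield_GYR=gyr, transplant_delay_days=delay + 7), cfg
        )
        assert ty_up >= ty
        assert ty_later <= ty


class TestNRate:
    @pytest.mark.parametrize("ty, expected", [(3.0, 57.0), (6.0, 123.0), (4.5, 90.0)])
    def test_calibration_line(self, cfg, ty, expected):
        assert n_rate(ty, cfg) == pytest.approx(expected)

    def test_terminal_segment_extrapolates_to_bounds(self, cfg):
        assert n_rate(6.5, cfg) == pytest.approx(123 + 22 * 0.5)

    def test_outside_bounds_rejected(self, cfg):
        with pytest.raises(ValueError):
            n_rate(2.9, cfg)
        with pytest.raises(ValueError):
            n_rate(6.6, cfg)

    def test_piecewise_linear_through_extra_anchor(self):
        cfg = EngineConfig(n_calibration_anchors=((3, 57), (5, 100), (6, 123)))
        assert n_rate(4.0, cfg) == pytest.approx(57 + (100 - 57) / 2)
        assert n_rate(5.5, cfg) == pytest.approx(100 + 23 / 2)

    @given(ty=st.floats(3.0, 6.5))
    @settings(max_examples=100, deadline=None)
    def test_non_decreasing(self, ty):
        cfg = EngineConfig()
        assert n_rate(min(ty + 0.1, 6.5), cfg) >= n_rate(ty, cfg)


class TestStageSchedule:
    def test_worked_example(self, cfg):
        basal, mt, pi = stage_schedule(140, 25, cfg)
        assert pi == 55 and mt == 28 and basal <= 16

    @pytest.mark.parametrize("duration, expected_basal", [(100, 5), (160, 21)])
    def test_basal_window_endpoints(self, cfg, duration, expected_basal):
        basal, _, _ = stage_schedule(duration, 18, cfg)
        assert basal == expected_basal

    def test_panicle_initiation_offset(self, cfg):
        assert stage_schedule(110, 20, cfg)[2] == 30

    def test_too_old_seedlings_rejected(self, cfg):
        with pytest.raises(SchedulingError):
            stage_schedule(100, 35, cfg)

    def test_strictly_increasing_and_age_shift(self, cfg):
        # brute-force sweep: stages strictly ordered and panicle
        # initiation slides one day earlier per extra nursery day
        for duration in range(100, 165, 5):
            previous_pi = None
            for age in range(12, 31):
                try:
                    basal, mt, pi = stage_schedule(duration, age, cfg)
                except SchedulingError:
                    previous_pi = None
                    continue
                assert basal < mt < pi
                assert pi == duration - 60 - age
                if previous_pi is not None:
                    assert pi == previous_pi - 1
                previous_pi = pi


class TestNSplits:
    @pytest.mark.parametrize(
        "fn, fractions, expected",
        [
            (100.0, (0.30, 0.30, 0.40), (30.0, 30.0, 40.0)),
            (0.0, (0.30, 0.30, 0.40), (0.0, 0.0, 0.0)),
            (80.0, (0.20, 0.50, 0.30), (16.0, 40.0, 24.0)),
        ],
    )
    def test_amounts(self, fn, fractions, expected):
        cfg = EngineConfig(n_split_fractions=fractions)
        assert n_split_amounts(fn, cfg) == pytest.approx(expected)

    def test_negative_rejected(self, cfg):
        with pytest.raises(ValueError):
            n_split_amounts(-1.0, cfg)

    @given(fn=st.floats(0, 250))
    @settings(max_examples=100, deadline=None)
    def test_exact_conservation(self, fn):
        cfg = EngineConfig()
        assert sum(n_split_amounts(fn, cfg)) == pytest.approx(fn, abs=1e-9)


class TestPRate:
    def test_balance_with_residue_credit(self, cfg):
        assert p_rate(5.0, 4.5, 0.15, cfg) == pytest.approx(12.4735, abs=1e-3)

    def test_no_previous_crop_means_no_credit(self, cfg):
        assert p_rate(4.0, 0.0, 0.15, cfg) == pytest.approx(cfg.rie_p * 4.0)

    def test_never_negative_and_linear_in_credit(self, cfg):
        huge_credit = p_rate(3.0, 50.0, 1.0, cfg)
        assert huge_credit == 0.0
        f0 = p_rate(5.0, 0.0, 0.15, cfg)
        f2 = p_rate(5.0, 2.0, 0.15, cfg)
        f4 = p_rate(5.0, 4.0, 0.15, cfg)
        assert f0 - f2 == pytest.approx(f2 - f4)
        assert f0 > f2 > f4

    def test_defaults_stay_in_observed_band(self, cfg):
        # engine P rates across the full target-yield range stay inside
        # the 6-21 kg/ha band observed for field-specific prescriptions
        for ty in np.arange(3.0, 6.51, 0.1):
            for prev in (0.0, 3.0, 6.3):
                assert 6.0 <= p_rate(ty, prev, 0.15, cfg) <= 21.0


class TestKRate:
    @pytest.mark.parametrize("ty, expected", [(3.0, 14.8), (6.0, 29.7)])
    def test_yield_gain_rule(self, cfg, ty, expected):
        assert k_rate(ty, cfg) == pytest.approx(expected, abs=0.05)

    def test_zero_gain_means_zero_k(self):
        cfg = EngineConfig(k_yield_gain_fraction=0.0)
        assert k_rate(5.0, cfg) == 0.0

    def test_scaling_structure(self, cfg):
        # linear in the gain fraction and uptake, inverse in recovery
        double_gain = EngineConfig(k_yield_gain_fraction=0.30)
        half_recovery = EngineConfig(k_recovery_efficiency=0.22)
        assert k_rate(5.0, double_gain) == pytest.approx(2 * k_rate(5.0, cfg))
        assert k_rate(5.0, half_recovery) == pytest.approx(2 * k_rate(5.0, cfg))

    def test_bad_recovery_rejected(self):
        with pytest.raises(ValueError):
            EngineConfig(k_recovery_efficiency=0.0)


class TestKSplits:
    @pytest.mark.parametrize(
        "fk, expected",
        [(28.0, (28.0,)), (33.0, (33.0,)), (34.0, (17.0, 17.0))],
    )
    def test_basal_threshold_inclusive(self, cfg, fk, expected):
        assert k_split_amounts(fk, cfg) == pytest.approx(expected)

    @given(fk=st.floats(0, 150))
    @settings(max_examples=100, deadline=None)
    def test_conservation_and_count(self, fk):
        cfg = EngineConfig()
        splits = k_split_amounts(fk, cfg)
        assert sum(splits) == pytest.approx(fk, abs=1e-9)
        assert len(splits) == (1 if fk <= cfg.k_basal_threshold else 2)


class TestBuildPrescription:
    def test_worked_example_composition(self, cfg, interview):
        rx = build_prescription(interview, cfg)
        assert rx.target_yield_GYT == pytest.approx(5.1)
        assert rx.fn == pytest.approx(103.2)
        assert rx.fp == pytest.approx(12.73, abs=0.01)
        assert rx.fk == pytest.approx(25.21, abs=0.01)
        assert len(rx.n_splits) == 3
        assert len(rx.k_splits) == 1  # 25.2 <= 33, all basal

    def test_low_history_floors_at_calibration_anchor(self, cfg):
        rx = build_prescription(make_interview(historical_yield_GYR=2.0), cfg)
        assert rx.target_yield_GYT == pytest.approx(3.0)
        assert rx.fn == pytest.approx(57.0)

    @given(
        gyr=st.floats(1.7, 6.3),
        duration=st.integers(100, 160),
        age=st.integers(12, 28),
        prev=st.floats(0, 6.3),
    )
    @settings(max_examples=150, deadline=None)
    def test_invariants_hold_for_any_valid_interview(self, gyr, duration, age, prev):
        cfg = EngineConfig()
        iv = make_interview(
            historical_yield_GYR=gyr,
            growth_duration_days=duration,
            seedling_age_days=min(age, duration - 73),
            previous_crop_yield=prev,
        )
        try:
            rx = build_prescription(iv, cfg)
        except SchedulingError:
            return
        assert cfg.ty_min <= rx.target_yield_GYT <= cfg.ty_max
        assert min(rx.fn, rx.fp, rx.fk) >= 0
        assert sum(s.amount for s in rx.n_splits) == pytest.approx(rx.fn, abs=1e-6)
        assert sum(s.amount for s in rx.k_splits) == pytest.approx(rx.fk, abs=1e-6)
        dats = [s.dat for s in rx.n_splits]
        assert dats == sorted(dats) and len(set(dats)) == 3
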