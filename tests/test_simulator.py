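"""Duty-cycle simulator: event arithmetic, energy accounting, invariants."""

import numpy as np
import pytest

from microgps import (
    BatteryState,
    GpsEnvironment,
    PowerModel,
    TagConfig,
    ValidationError,
    apply_rtc_drift,
    battery_limited_runtime,
    benchmark_row,
    benchmark_setup,
    effective_fix_rate,
    memory_limited_duration,
    simulate,
)


def det_env(**kw) -> GpsEnvironment:
    kw.setdefault("deterministic", True)
    return GpsEnvironment(**kw)


class TestScheduleArithmetic:
    def test_effective_rate_single_five_minutes(self):
        assert effective_fix_rate(TagConfig(interval_s=300)) == pytest.approx(1 / 300)

    def test_effective_rate_burst(self):
        cfg = TagConfig(interval_s=1, burst_len_s=10, burst_gap_s=30)
        assert effective_fix_rate(cfg) == pytest.approx(0.25)

    def test_effective_rate_continuous(self):
        assert effective_fix_rate(TagConfig(interval_s=1)) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "cfg,hours",
        [
            (TagConfig(interval_s=1), 3.6),
            (TagConfig(interval_s=5), 18.2),
            (TagConfig(interval_s=1, burst_len_s=10, burst_gap_s=30), 14.6),
        ],
    )
    def test_memory_limited_duration_matches_capacity_arithmetic(self, cfg, hours):
        assert memory_limited_duration(13100, cfg) == hours

    def test_battery_limited_runtime(self):
        assert battery_limited_runtime(30, 10.6) == pytest.approx(2.83, abs=0.005)
        assert battery_limited_runtime(30, 1.8) == pytest.approx(16.7, abs=0.05)
        for c in (0.5, 7.0, 42.0):
            assert battery_limited_runtime(c, c) == 1.0

    def test_rtc_drift(self):
        assert apply_rtc_drift(3600, 0.0) == 3600
        assert apply_rtc_drift(3600, 0.03) == pytest.approx(3708)
        with pytest.raises(ValidationError):
            apply_rtc_drift(3600, 0.05)

    def test_burst_without_gap_rejected(self):
        with pytest.raises((ValidationError, ValueError)):
            TagConfig(interval_s=1, burst_len_s=10, burst_gap_s=0)


class TestSimulate:
    def test_continuous_mode_calibrated_against_benchmark_headline(self):
        # 1 Hz continuous, TTFF 64 s, measured 10.6 mA on 30 mAh
        cfg, power, battery, env = benchmark_setup(
            benchmark_row("1 s"), deterministic=True
        )
        res = simulate(cfg, power, battery, env)
        assert res.stop_reason == "battery"
        assert res.runtime_h == pytest.approx(30 / 10.6, rel=1e-3)
        assert 2.7 < res.runtime_h < 2.9
        assert 10100 <= res.n_fixes <= 10200
        assert res.n_fixes == pytest.approx(10190, rel=0.05)

    def test_zero_capacity_battery_stops_immediately(self):
        res = simulate(TagConfig(interval_s=60), battery=BatteryState(capacity_mah=0),
                       env=det_env())
        assert res.n_fixes == 0
        assert res.stop_reason == "battery"
        assert res.runtime_h == 0

    def test_fix_failure_spacing_follows_timeout_plus_retry_sleep(self):
        env = det_env(p_fix_given_utc=0.0)
        res = simulate(
            TagConfig(interval_s=60), battery=BatteryState(capacity_mah=6), env=env
        )
        assert res.n_fixes == 0
        assert all(a.outcome == "timeout_no_fix" for a in res.attempts)
        starts = [a.t_start_s for a in res.attempts]
        assert len(starts) >= 3
        # 300 s timeout + 900 s hibernation between attempt starts
        assert np.allclose(np.diff(starts), 1200.0)

    def test_no_utc_timeout_uses_short_timeout(self):
        env = det_env(p_utc=0.0)
        res = simulate(
            TagConfig(interval_s=60), battery=BatteryState(capacity_mah=3), env=env
        )
        assert res.n_fixes == 0
        assert all(a.outcome == "timeout_no_utc" for a in res.attempts)
        assert all(a.duration_s == 120.0 for a in res.attempts)

    def test_charge_conservation_in_trace(self):
        cfg, power, battery, env = benchmark_setup(benchmark_row("30 s"), seed=3)
        res = simulate(cfg, power, battery, env)
        integrated = sum(seg.charge_mah for seg in res.trace)
        assert integrated == pytest.approx(res.charge_used_mah, rel=1e-3)
        for seg in res.trace:
            assert seg.charge_mah == pytest.approx(
                seg.current_ma * seg.duration_s / 3600, rel=1e-9, abs=1e-12
            )

    def test_native_power_charge_conservation(self):
        res = simulate(
            TagConfig(interval_s=120),
            battery=BatteryState(capacity_mah=2),
            env=det_env(),
        )
        integrated = sum(seg.charge_mah for seg in res.trace)
        assert integrated == pytest.approx(res.charge_used_mah, rel=1e-3)
        assert res.avg_current_ma * res.runtime_h == pytest.approx(
            res.charge_used_mah, rel=1e-6
        )

    def test_longer_interval_never_shortens_runtime(self):
        runtimes = []
        for interval in (30, 120, 600):
            res = simulate(
                TagConfig(interval_s=interval),
                battery=BatteryState(capacity_mah=2),
                env=det_env(),
            )
            runtimes.append(res.runtime_h)
        assert runtimes == sorted(runtimes)

    def test_larger_battery_never_records_fewer_fixes(self):
        counts = []
        for mah in (1, 2, 4):
            res = simulate(
                TagConfig(interval_s=60),
                battery=BatteryState(capacity_mah=mah),
                env=det_env(),
            )
            counts.append(res.n_fixes)
        assert counts == sorted(counts)

    def test_memory_full_stops_at_exact_capacity(self):
        res = simulate(
            TagConfig(interval_s=30),
            battery=BatteryState(capacity_mah=1000),
            env=det_env(),
            capacity_fixes=50,
        )
        assert res.stop_reason == "memory"
        assert res.n_fixes == 50

    def test_identical_seeds_reproduce_identical_results(self):
        def run():
            cfg, power, battery, env = benchmark_setup(benchmark_row("1 min"), seed=7)
            return simulate(cfg, power, battery, env)

        a, b = run(), run()
        assert a.n_fixes == b.n_fixes
        assert a.runtime_h == b.runtime_h
        assert [x.duration_s for x in a.attempts] == [x.duration_s for x in b.attempts]

    def test_rtc_drift_delays_window_opening(self):
        # tag activated at midnight; 8 h nominal sleep to a 08:00 window
        # running +3% slow opens 14.4 min late
        cfg = TagConfig(
            interval_s=60,
            window_start_min=480,
            window_end_min=600,
            rtc_error_frac=0.03,
        )
        res = simulate(cfg, battery=BatteryState(capacity_mah=0.5), env=det_env())
        first_sleep = res.trace[0]
        assert first_sleep.state == "inactive"
        assert first_sleep.duration_s == pytest.approx(8 * 3600 * 1.03)
        assert res.attempts[0].t_start_s - 8 * 3600 == pytest.approx(14.4 * 60)

    def test_geofence_suppression_consumes_energy_but_not_memory(self):
        cfg = TagConfig(interval_s=60, geofence_enabled=True, geofence_radius_m=300)
        res = simulate(cfg, battery=BatteryState(capacity_mah=1), env=det_env())
        # stationary site: home stored, every later fix suppressed
        assert res.n_fixes == 1
        assert res.suppressed_fixes > 0
        assert any(seg.state == "geofence_hold" for seg in res.trace)


class TestBenchmarkCalibration:
    def test_all_rows_within_ten_percent(self):
        from microgps import BENCHMARK

        for i, row in enumerate(BENCHMARK):
            cfg, power, battery, env = benchmark_setup(row, seed=11 + i)
            res = simulate(cfg, power, battery, env)
            assert res.n_fixes == pytest.approx(row.avg_fixes, rel=0.10), row.label
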