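"""Performance statistics: summaries, location errors, efficiency, deltas."""

import math

import numpy as np
import pandas as pd
import pytest

from microgps import (
    Attempt,
    PerfSummary,
    ValidationError,
    fixes_per_gram,
    fixes_per_mah,
    location_errors,
    mode_comparison,
    summarize,
)
from microgps.benchmark import BENCHMARK


def fix_attempt(t, dur, cold=False, hdop=1.5):
    return Attempt(t, "fix", dur, cold, hdop)


class TestSummarize:
    def test_single_successful_attempt(self):
        s = summarize([fix_attempt(0, 64, cold=True)])
        assert s.ttff_s == 64
        assert s.mean_ttf_s == 64
        assert s.fix_success_rate_pct == 100.0
        assert s.n_fixes == 1

    def test_success_rate_arithmetic(self):
        attempts = [fix_attempt(i * 100, 10, cold=(i == 0)) for i in range(9)]
        attempts.append(Attempt(900, "timeout_no_fix", 300, False))
        s = summarize(attempts)
        assert s.fix_success_rate_pct == pytest.approx(90.0)

    def test_mean_ttf_pools_cold_and_hot_starts(self):
        attempts = [fix_attempt(0, 90, cold=True)] + [
            fix_attempt(60 * (i + 1), 10) for i in range(7)
        ]
        s = summarize(attempts)
        assert s.ttff_s == 90
        assert s.mean_ttf_s == pytest.approx((90 + 7 * 10) / 8)

    def test_mean_hdop_over_successes_only(self):
        attempts = [
            fix_attempt(0, 60, cold=True, hdop=1.0),
            Attempt(100, "timeout_no_utc", 120, False, None),
            fix_attempt(200, 10, hdop=3.0),
        ]
        assert summarize(attempts).mean_hdop == pytest.approx(2.0)

    def test_permutation_invariant(self):
        attempts = [fix_attempt(t, 5 + t % 7, cold=(t == 0)) for t in range(0, 600, 60)]
        shuffled = list(reversed(attempts))
        assert summarize(attempts) == summarize(sorted(shuffled, key=lambda a: a.t_start_s))

    def test_empty_log_rejected(self):
        with pytest.raises(ValidationError):
            summarize([])


def track_frame(n, lon_shift=0.0, t0=0):
    utc = pd.to_datetime(np.arange(n) + t0, unit="s", utc=True)
    return pd.DataFrame(
        {"utc": utc, "lat": np.zeros(n), "lon": np.linspace(0, 0.001, n) + lon_shift}
    )


class TestLocationErrors:
    def test_identical_tracks_have_zero_error(self):
        t = track_frame(100)
        _, mean, unpaired = location_errors(t, t)
        assert mean == 0.0
        assert unpaired == 0

    def test_longitude_shift_at_equator(self):
        t = track_frame(50)
        ref = track_frame(50, lon_shift=0.001)
        _, mean, _ = location_errors(t, ref)
        assert mean == pytest.approx(111.195, rel=1e-4)

    def test_rayleigh_mean_for_isotropic_noise(self):
        # isotropic 10 m per-axis noise → mean radial error 10·sqrt(pi/2)
        n = 10_000
        rng = np.random.default_rng(5)
        t = track_frame(n)
        deg = 180 / math.pi / 6_371_000
        ref = t.copy()
        t = t.assign(
            lat=t["lat"] + rng.normal(0, 10, n) * deg,
            lon=t["lon"] + rng.normal(0, 10, n) * deg,
        )
        _, mean, _ = location_errors(t, ref)
        expect = 10 * math.sqrt(math.pi / 2)
        se = 10 * math.sqrt((4 - math.pi) / 2) / math.sqrt(n)
        assert abs(mean - expect) < 3 * se

    def test_pairing_respects_max_gap(self):
        t = track_frame(10)
        ref = track_frame(10, t0=100)  # all reference fixes 100 s away
        with pytest.warns(UserWarning):
            pairs, mean, unpaired = location_errors(t, ref, max_gap_s=2)
        assert mean is None
        assert unpaired == 10


class TestEfficiencyRatios:
    def test_dog_walk_ratios(self):
        assert fixes_per_mah(11953, 30) == 398
        assert fixes_per_gram(11953, 2.45) == 4879

    def test_bat_ratios(self):
        assert fixes_per_mah(188, 30) == 6.3
        assert fixes_per_gram(410, 1.3) == 315

    def test_best_case_mass_ratio(self):
        assert fixes_per_gram(10190, 1.3) == 7838

    def test_zero_fixes(self):
        assert fixes_per_mah(0, 30) == 0.0

    def test_non_positive_denominators_rejected(self):
        with pytest.raises(ValidationError):
            fixes_per_mah(10, 0)
        with pytest.raises(ValidationError):
            fixes_per_gram(10, -1)


def benchmark_groups():
    groups = {"high": [], "single": []}
    for row in BENCHMARK:
        s = PerfSummary(
            n_fixes=int(row.avg_fixes),
            ttff_s=row.ttff_s,
            mean_ttf_s=row.ttf_s,
            mean_hdop=row.avg_hdop,
            fix_success_rate_pct=row.fix_success_pct,
            mean_location_error_m=row.avg_location_error_m,
            runtime_h=row.runtime_h,
            avg_current_ma=row.avg_current_ma,
        )
        groups["high" if row.high_frequency else "single"].append(s)
    return groups


class TestModeComparison:
    def test_benchmark_deltas(self):
        deltas = mode_comparison(benchmark_groups(), baseline="single")["high"]
        assert deltas["location_error_pct"] == -49
        assert deltas["time_to_fix_pct"] == -34
        assert deltas["fixes_per_mah_pct"] == 1349

    def test_identical_groups_give_zero(self):
        g = benchmark_groups()["single"]
        deltas = mode_comparison({"a": g, "b": list(g)}, baseline="a")["b"]
        assert set(deltas.values()) == {0}

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mode_comparison({"a": benchmark_groups()["single"], "b": []}, baseline="a")
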