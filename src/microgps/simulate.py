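"""Discrete-event simulation of the logger's duty-cycle state machine.

The tag cycles through a small number of power states: acquiring a
position (~14.5 mA whole-tag), continuously tracking in the receiver's
fitness low-power mode (~9.5 mA, used for 1–5 s fix intervals and
within 1 Hz bursts), idling between hot-start fixes with only the GPS
backup domain powered (~8 µA), and hibernating outside the daily
recording window (<500 nA).  A coulomb-counted battery and a
fixed-capacity memory image bound the run; the simulation ends at
whichever limit is hit first.

Scheduling rules modelled (all configurable):

* a fix attempt is abandoned after 120 s without UTC digitisation, or
  after 300 s with UTC but no position; a failed attempt is followed by
  a 15-minute hibernation regardless of the configured interval;
* after the first fix of a day (cold start) the receiver stays powered
  an extra 30 s to collect satellite data for faster hot starts;
* after each position estimate the tag waits up to 9 s for the HDOP to
  drop below a configurable target before storing;
* daily recording windows have minute resolution and are timed by an
  RTC with a configurable fractional drift (±3 % bound);
* bursts record ``burst_len_s`` consecutive 1 Hz fixes and then sleep
  for ``burst_gap_s`` (the gap convention: a "10 s burst every 30 s"
  sleeps 30 s *after* each burst);
* optional geofencing suppresses storage of fixes within a radius of
  the first fix and instead holds for 10 minutes (the suppressed
  acquisition still costs energy).

HDOP settling model
-------------------
The per-attempt HDOP-refinement wait is not a constant: after a long
off-gap the receiver's first estimate has an inflated HDOP that decays
toward the site's settled level as more satellites are re-acquired.
The environment models the first-estimate HDOP as
``settled * (1 + gap/tau_stale)`` and the decay as exponential with
time constant ``tau_settle``; the wait ends when the curve crosses the
target (capped at the 9 s maximum).  Defaults ``tau_stale = 40 s`` and
``tau_settle = 12 s`` are calibrated against the published stationary
benchmark (see :mod:`microgps.benchmark` and ``docs/methods.md``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import codec
from .benchmark import MODE_BURST, MODE_CONTINUOUS, MODE_SINGLE, BenchmarkRow
from .codec import GpsFix, MemoryImage
from .errors import MemoryFullError, ValidationError
from .geofence import haversine_m
from .trackstats import Attempt

__all__ = [
    "TagConfig",
    "PowerModel",
    "BatteryState",
    "GpsEnvironment",
    "SimResult",
    "simulate",
    "effective_fix_rate",
    "memory_limited_duration",
    "battery_limited_runtime",
    "apply_rtc_drift",
    "benchmark_setup",
]


# ---------------------------------------------------------------------------
# configuration models


class TagConfig(BaseModel):
    """Full logger configuration.

    The recording mode is implied by the schedule fields: a positive
    ``burst_len_s`` selects burst mode; otherwise intervals of at most
    ``flp_interval_max_s`` run the receiver continuously (FLP mode) and
    longer intervals use single-fix duty cycling.
    """

    interval_s: float = Field(300.0, gt=0)
    burst_len_s: float = Field(0.0, ge=0)
    burst_gap_s: float = Field(0.0, ge=0)
    window_start_min: Optional[int] = Field(None, ge=0, lt=1440)
    window_end_min: Optional[int] = Field(None, ge=0, lt=1440)
    hdop_target: float = Field(3.0, gt=0)
    hdop_wait_max_s: float = Field(9.0, ge=0)
    timeout_no_utc_s: float = Field(120.0, gt=0)
    timeout_no_fix_s: float = Field(300.0, gt=0)
    retry_sleep_s: float = Field(900.0, gt=0)
    post_coldstart_listen_s: float = Field(30.0, ge=0)
    flp_interval_max_s: float = Field(5.0, gt=0)
    cutoff_voltage_v: float = Field(3.3, gt=0)
    geofence_enabled: bool = False
    geofence_radius_m: float = Field(300.0, gt=0)
    geofence_hold_s: float = Field(600.0, ge=0)
    rtc_error_frac: float = Field(0.0, ge=-0.03, le=0.03)

    @model_validator(mode="after")
    def _check_schedule(self) -> "TagConfig":
        if self.burst_len_s > 0 and self.burst_gap_s <= 0:
            raise ValidationError("burst mode needs a positive burst_gap_s")
        if self.burst_len_s > 0 and self.burst_len_s < 1:
            raise ValidationError("burst_len_s must cover at least one 1 Hz fix")
        if (self.window_start_min is None) != (self.window_end_min is None):
            raise ValidationError("set both window bounds or neither")
        return self

    @property
    def mode(self) -> str:
        if self.burst_len_s > 0:
            return MODE_BURST
        if self.interval_s <= self.flp_interval_max_s:
            return MODE_CONTINUOUS
        return MODE_SINGLE


class PowerModel(BaseModel):
    """Stated whole-tag current draws plus calibration knobs.

    ``overhead_mc_per_fix`` charges a fixed number of millicoulombs per
    stored fix (EEPROM writes, MCU bookkeeping).  When
    ``avg_current_override_ma`` is set, battery depletion while the tag
    is on duty is accounted at that constant measured current instead of
    the per-state sums — the calibration path used to match a measured
    discharge (measured average currents exceed naive component sums).
    """

    i_acquire_ma: float = Field(14.5, ge=0)
    i_flp_ma: float = Field(9.5, ge=0)
    i_idle_ua: float = Field(8.0, ge=0)
    i_inactive_na: float = Field(500.0, ge=0)
    i_mcu_active_ma: float = Field(0.7, ge=0)
    overhead_mc_per_fix: float = Field(0.0, ge=0)
    avg_current_override_ma: Optional[float] = Field(None, gt=0)

    @property
    def i_idle_ma(self) -> float:
        return self.i_idle_ua / 1000.0

    @property
    def i_inactive_ma(self) -> float:
        return self.i_inactive_na / 1e6


@dataclass
class BatteryState:
    """Coulomb-counted battery.

    ``usable_frac`` scales nominal capacity to the charge extractable
    above the low-voltage cutoff (default: all of it).
    """

    capacity_mah: float = 30.0
    charge_used_mah: float = 0.0
    usable_frac: float = 1.0

    def __post_init__(self) -> None:
        if self.capacity_mah < 0 or not 0 < self.usable_frac <= 1:
            raise ValidationError("invalid battery parameters")

    @property
    def usable_mah(self) -> float:
        return self.capacity_mah * self.usable_frac

    @property
    def exhausted(self) -> bool:
        return self.charge_used_mah >= self.usable_mah


@dataclass
class GpsEnvironment:
    """Stochastic model of acquisition times, success and HDOP.

    Cold-start TTFF and hot-start TTF are log-normal (parameterised by
    median and log-sd); HDOP draws are gamma with a configurable mean
    and shape.  ``p_utc`` and ``p_fix_given_utc`` gate the two timeout
    paths.  With ``deterministic=True`` every draw returns its central
    value (medians/means), which makes event arithmetic exactly
    reproducible by hand.
    """

    ttff_median_s: float = 90.0
    ttff_log_sd: float = 0.4
    ttf_median_s: float = 8.0
    ttf_log_sd: float = 0.3
    p_utc: float = 1.0
    p_fix_given_utc: float = 1.0
    hdop_mean: float = 1.8
    hdop_shape: float = 10.0
    hdop_stale_tau_s: float = 40.0
    hdop_settle_tau_s: float = 12.0
    site_lat: float = 47.69
    site_lon: float = 9.19
    deterministic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_utc, self.p_fix_given_utc):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must lie in [0, 1]")
        self._rng = np.random.default_rng(self.seed)

    # -- draws --------------------------------------------------------------
    def draw_ttff_s(self) -> float:
        if self.deterministic:
            return self.ttff_median_s
        return float(self._rng.lognormal(math.log(self.ttff_median_s), self.ttff_log_sd))

    def draw_ttf_s(self) -> float:
        if self.deterministic:
            return self.ttf_median_s
        return float(self._rng.lognormal(math.log(self.ttf_median_s), self.ttf_log_sd))

    def draw_utc_ok(self) -> bool:
        return self.p_utc >= 1.0 or (
            not self.deterministic and self._rng.random() < self.p_utc
        )

    def draw_fix_ok(self) -> bool:
        return self.p_fix_given_utc >= 1.0 or (
            not self.deterministic and self._rng.random() < self.p_fix_given_utc
        )

    def draw_hdop(self) -> float:
        if self.deterministic or self.hdop_shape <= 0:
            return self.hdop_mean
        return float(
            self._rng.gamma(self.hdop_shape, self.hdop_mean / self.hdop_shape)
        )

    # -- HDOP settling ------------------------------------------------------
    def hdop_wait_s(self, off_gap_s: float, target: float, cap_s: float) -> float:
        """Refinement wait after an acquisition that followed an off-gap.

        Deterministic settling curve of the *mean* HDOP level: the first
        estimate sits at ``mean * (1 + gap/tau_stale)`` and decays
        exponentially toward ``mean``; the wait is the crossing time of
        the target, capped at ``cap_s``.
        """
        m = self.hdop_mean
        if math.isinf(off_gap_s):
            initial = math.inf
        else:
            initial = m * (1.0 + off_gap_s / self.hdop_stale_tau_s)
        if initial <= target:
            return 0.0
        if m >= target:
            return cap_s
        if math.isinf(initial):
            return cap_s
        t_cross = self.hdop_settle_tau_s * math.log((initial - m) / (target - m))
        return min(cap_s, max(0.0, t_cross))


# ---------------------------------------------------------------------------
# results


@dataclass
class TraceSegment:
    t0_s: float
    duration_s: float
    current_ma: float
    charge_mah: float
    state: str


@dataclass
class SimResult:
    """Outcome of one simulated deployment."""

    fixes: list[GpsFix]
    attempts: list[Attempt]
    trace: list[TraceSegment]
    runtime_h: float
    charge_used_mah: float
    stop_reason: str  # battery | memory | window_end
    suppressed_fixes: int = 0

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def avg_current_ma(self) -> float:
        return self.charge_used_mah / self.runtime_h if self.runtime_h > 0 else 0.0

    def summary(self) -> dict:
        """Headline numbers, named like the benchmark table columns."""
        succ = [a for a in self.attempts if a.outcome == "fix"]
        cold = [a for a in succ if a.is_cold_start]
        hd = [a.hdop for a in succ if a.hdop is not None]
        return {
            "Avg. fixes": self.n_fixes,
            "Avg. time to first fix (s)": cold[0].duration_s if cold else None,
            "Avg. time to fix (s)": (
                sum(a.duration_s for a in succ) / len(succ) if succ else None
            ),
            "Avg. HDOP": sum(hd) / len(hd) if hd else None,
            "Avg. fix success rate (%)": (
                100.0 * len(succ) / len(self.attempts) if self.attempts else None
            ),
            "Avg. runtime (hrs)": self.runtime_h,
            "Avg. current (mA)": self.avg_current_ma,
            "stop_reason": self.stop_reason,
        }


# ---------------------------------------------------------------------------
# engine


class _BatteryDead(Exception):
    pass


class _Engine:
    def __init__(self, config, power, battery, env, capacity_fixes, start_utc_s, track):
        self.cfg = config
        self.pw = power
        self.bat = battery
        self.env = env
        self.capacity_fixes = capacity_fixes
        self.start_utc_s = start_utc_s
        self.track = track
        self.t = 0.0
        self.trace: list[TraceSegment] = []
        self.fixes: list[GpsFix] = []
        self.attempts: list[Attempt] = []
        self.suppressed = 0
        self.home: GpsFix | None = None
        self.gps_off_since = 0.0  # start of the current off-gap

    # -- energy -------------------------------------------------------------
    def spend(self, duration_s: float, current_ma: float, state: str) -> None:
        """Advance time, accruing charge; truncate at battery exhaustion."""
        if duration_s <= 0:
            return
        if self.pw.avg_current_override_ma is not None and state != "inactive":
            current_ma = self.pw.avg_current_override_ma
        left = self.bat.usable_mah - self.bat.charge_used_mah
        charge = current_ma * duration_s / 3600.0
        if charge >= left:
            if current_ma > 0:
                duration_s = left / current_ma * 3600.0
                charge = left
            self.trace.append(TraceSegment(self.t, duration_s, current_ma, charge, state))
            self.t += duration_s
            self.bat.charge_used_mah = self.bat.usable_mah
            raise _BatteryDead
        self.trace.append(TraceSegment(self.t, duration_s, current_ma, charge, state))
        self.t += duration_s
        self.bat.charge_used_mah += charge

    def spend_overhead(self) -> None:
        if self.pw.overhead_mc_per_fix <= 0:
            return
        charge = self.pw.overhead_mc_per_fix / 3600.0  # mC -> mAh
        left = self.bat.usable_mah - self.bat.charge_used_mah
        if charge >= left:
            self.bat.charge_used_mah = self.bat.usable_mah
            self.trace.append(TraceSegment(self.t, 0.0, 0.0, left, "store"))
            raise _BatteryDead
        self.bat.charge_used_mah += charge
        self.trace.append(TraceSegment(self.t, 0.0, 0.0, charge, "store"))

    # -- fixes --------------------------------------------------------------
    def position(self) -> tuple[float, float]:
        if self.track is not None:
            return self.track(self.t)
        return self.env.site_lat, self.env.site_lon

    def store_fix(self, hdop: float | None) -> bool:
        """Record a fix, honouring geofencing and memory capacity.

        Returns False when the fix was suppressed by the geofence (the
        hibernation hold has then already been charged).
        """
        lat, lon = self.position()
        fix = GpsFix(utc=self.start_utc_s + int(round(self.t)), lat=lat, lon=lon, hdop=hdop)
        if self.cfg.geofence_enabled:
            if self.home is None:
                self.home = fix
            else:
                d = haversine_m(self.home.lat, self.home.lon, fix.lat, fix.lon)
                if d <= self.cfg.geofence_radius_m:
                    self.suppressed += 1
                    self.spend(self.cfg.geofence_hold_s, self.pw.i_idle_ma, "geofence_hold")
                    return False
        if len(self.fixes) >= self.capacity_fixes:
            raise MemoryFullError(f"memory full at {len(self.fixes)} fixes")
        self.fixes.append(fix)
        self.spend_overhead()
        return True

    # -- attempts -----------------------------------------------------------
    def attempt(self, cold: bool) -> Attempt | None:
        """One acquisition attempt; returns the record, or None on failure
        (after charging the timeout and logging it)."""
        gap = self.t - self.gps_off_since if not cold else math.inf
        t0 = self.t
        if not self.env.draw_utc_ok():
            self.spend(self.cfg.timeout_no_utc_s, self.pw.i_acquire_ma, "acquire")
            a = Attempt(t0, "timeout_no_utc", self.cfg.timeout_no_utc_s, cold, None)
            self.attempts.append(a)
            return None
        if not self.env.draw_fix_ok():
            self.spend(self.cfg.timeout_no_fix_s, self.pw.i_acquire_ma, "acquire")
            a = Attempt(t0, "timeout_no_fix", self.cfg.timeout_no_fix_s, cold, None)
            self.attempts.append(a)
            return None
        dur = self.env.draw_ttff_s() if cold else self.env.draw_ttf_s()
        dur = min(dur, self.cfg.timeout_no_fix_s)
        self.spend(dur, self.pw.i_acquire_ma, "acquire")
        wait = self.env.hdop_wait_s(gap, self.cfg.hdop_target, self.cfg.hdop_wait_max_s)
        self.spend(wait, self.pw.i_acquire_ma, "hdop_wait")
        a = Attempt(t0, "fix", dur, cold, self.env.draw_hdop(), hdop_wait_s=wait)
        self.attempts.append(a)
        return a

    def gps_off(self) -> None:
        self.gps_off_since = self.t


# ---------------------------------------------------------------------------
# top-level operations


def apply_rtc_drift(nominal_s: float, drift_frac: float, max_frac: float = 0.03) -> float:
    """Duration actually slept when the RTC runs fast/slow by ``drift_frac``."""
    if abs(drift_frac) > max_frac:
        raise ValidationError(f"RTC drift {drift_frac} exceeds ±{max_frac}")
    return nominal_s * (1.0 + drift_frac)


def effective_fix_rate(schedule: TagConfig) -> float:
    """Long-run stored-fix rate in Hz implied by a schedule.

    Single-fix and continuous schedules yield ``1/interval_s``; bursts
    yield ``burst_len_s`` 1 Hz fixes per ``burst_len_s + burst_gap_s``.
    """
    if schedule.burst_len_s > 0:
        return schedule.burst_len_s / (schedule.burst_len_s + schedule.burst_gap_s)
    return 1.0 / schedule.interval_s


def memory_limited_duration(capacity_fixes: int, schedule: TagConfig) -> float:
    """Hours of recording until the memory fills, at 0.1 h resolution."""
    if capacity_fixes <= 0:
        raise ValidationError("capacity must be positive")
    rate = effective_fix_rate(schedule)
    if rate <= 0:
        raise ValidationError("schedule has zero effective fix rate")
    return round(capacity_fixes / rate / 3600.0, 1)


def battery_limited_runtime(capacity_mah: float, avg_current_ma: float) -> float:
    """Hours until a battery of ``capacity_mah`` is drained at the given
    average current."""
    if capacity_mah <= 0 or avg_current_ma <= 0:
        raise ValidationError("capacity and current must be positive")
    return capacity_mah / avg_current_ma


def simulate(
    config: TagConfig,
    power: PowerModel | None = None,
    battery: BatteryState | None = None,
    env: GpsEnvironment | None = None,
    capacity_fixes: int | None = None,
    *,
    start_utc_s: int = 0,
    max_sim_s: float = 120 * 24 * 3600.0,
    track: Callable[[float], tuple[float, float]] | None = None,
) -> SimResult:
    """Run the duty-cycle state machine until battery or memory stops it.

    ``track`` optionally maps simulation time (s) to a (lat, lon) the
    receiver would report; by default the tag sits at the environment's
    stationary site.  ``max_sim_s`` bounds pathological configurations
    (stop reason ``window_end``).
    """
    power = power or PowerModel()
    battery = battery if battery is not None else BatteryState()
    env = env or GpsEnvironment()
    if capacity_fixes is None:
        capacity_fixes = codec.eeprom_capacity()
    eng = _Engine(config, power, battery, env, capacity_fixes, start_utc_s, track)
    stop = "window_end"
    try:
        if battery.exhausted:
            raise _BatteryDead
        _run(eng, config, power, env, max_sim_s)
    except _BatteryDead:
        stop = "battery"
    except MemoryFullError:
        stop = "memory"
    return SimResult(
        fixes=eng.fixes,
        attempts=eng.attempts,
        trace=eng.trace,
        runtime_h=eng.t / 3600.0,
        charge_used_mah=battery.charge_used_mah,
        stop_reason=stop,
        suppressed_fixes=eng.suppressed,
    )


def _window_bounds_s(cfg: TagConfig) -> tuple[float, float] | None:
    if cfg.window_start_min is None:
        return None
    start = cfg.window_start_min * 60.0
    end = cfg.window_end_min * 60.0
    if end <= start:
        end += 86400.0  # window crosses midnight
    return start, end


def _run(eng: _Engine, cfg: TagConfig, pw: PowerModel, env: GpsEnvironment, max_sim_s: float) -> None:
    window = _window_bounds_s(cfg)
    while eng.t < max_sim_s:
        if window is not None:
            _sleep_to_window_open(eng, cfg, window)
            window_close = (eng.t // 86400.0) * 86400.0 + window[1]
        else:
            window_close = max_sim_s
        cold = True
        while eng.t < min(window_close, max_sim_s):
            a = eng.attempt(cold)
            if a is None:
                eng.gps_off()
                eng.spend(
                    apply_rtc_drift(cfg.retry_sleep_s, cfg.rtc_error_frac),
                    pw.i_idle_ma,
                    "retry_sleep",
                )
                continue
            if cfg.mode == MODE_CONTINUOUS:
                _run_continuous(eng, cfg, pw, env, min(window_close, max_sim_s))
                cold = False
                continue
            if cfg.mode == MODE_BURST:
                n = int(cfg.burst_len_s)
                for i in range(n):
                    eng.store_fix(env.draw_hdop() if i else a.hdop)
                    eng.spend(1.0, pw.i_acquire_ma, "burst")
                after_sleep = cfg.burst_gap_s
            else:  # single fix
                stored = eng.store_fix(a.hdop)
                # a geofence hold replaces the normal interval sleep
                after_sleep = cfg.interval_s if stored else 0.0
            if cold:
                eng.spend(cfg.post_coldstart_listen_s, pw.i_acquire_ma, "coldstart_listen")
                cold = False
            eng.gps_off()
            eng.spend(
                apply_rtc_drift(after_sleep, cfg.rtc_error_frac), pw.i_idle_ma, "idle"
            )
        if window is None:
            return  # ran to max_sim_s without window cycling


def _sleep_to_window_open(eng: _Engine, cfg: TagConfig, window: tuple[float, float]) -> None:
    day_start = (eng.t // 86400.0) * 86400.0
    open_t = day_start + window[0]
    if eng.t >= open_t:
        open_t += 86400.0
    nominal = open_t - eng.t
    eng.spend(
        apply_rtc_drift(nominal, cfg.rtc_error_frac), eng.pw.i_inactive_ma, "inactive"
    )


def _run_continuous(eng: _Engine, cfg: TagConfig, pw: PowerModel, env: GpsEnvironment, until: float) -> None:
    """Receiver held powered (FLP); fixes arrive every ``interval_s``."""
    while eng.t < until:
        eng.spend(cfg.interval_s, pw.i_flp_ma, "flp")
        eng.store_fix(env.draw_hdop())


# ---------------------------------------------------------------------------
# calibration helpers


def benchmark_setup(
    row: BenchmarkRow, seed: int = 0, deterministic: bool = False
) -> tuple[TagConfig, PowerModel, BatteryState, GpsEnvironment]:
    """Configuration, power, battery and environment matching one row of
    the published stationary benchmark.

    The row's measured average current becomes the battery-depletion
    override, and its TTFF/TTF/HDOP averages parameterise the
    environment — the per-row calibration under which simulated fix
    counts are expected to track the printed ones.
    """
    cfg = TagConfig(
        interval_s=row.interval_s,
        burst_len_s=row.burst_len_s,
        burst_gap_s=row.burst_gap_s,
    )
    power = PowerModel(avg_current_override_ma=row.avg_current_ma)
    battery = BatteryState(capacity_mah=30.0)
    env = GpsEnvironment(
        ttff_median_s=row.ttff_s,
        ttf_median_s=row.ttf_s if row.ttf_s is not None else 8.0,
        hdop_mean=row.avg_hdop,
        seed=seed,
        deterministic=deterministic,
    )
    return cfg, power, battery, env
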