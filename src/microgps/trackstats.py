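"""Performance statistics for GPS logger deployments.

Covers the metrics the logger computes on board (TTFF, average time to
fix, average HDOP, fix success rate), location-error evaluation of a
track against a reference track (nearest-in-time pairing, great-circle
distances), battery/mass efficiency ratios, and the high-frequency
versus single-fix mode comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geofence import haversine_m

OUTCOMES = ("fix", "timeout_no_utc", "timeout_no_fix")


@dataclass(frozen=True)
class Attempt:
    """One acquisition attempt from the tag's log.

    ``duration_s`` is the acquisition time alone; the optional HDOP
    refinement wait that follows a successful acquisition is reported
    separately in ``hdop_wait_s`` (whether on-board statistics include
    it in "time to fix" varies, so both views stay available).
    """

    t_start_s: float
    outcome: str
    duration_s: float
    is_cold_start: bool
    hdop: float | None = None
    hdop_wait_s: float = 0.0

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.duration_s < 0:
            raise ValidationError("negative attempt duration")


@dataclass(frozen=True)
class PerfSummary:
    """Headline performance metrics of one deployment or test."""

    n_fixes: int
    ttff_s: float | None
    mean_ttf_s: float | None
    mean_hdop: float | None
    fix_success_rate_pct: float
    mean_location_error_m: float | None = None
    runtime_h: float | None = None
    avg_current_ma: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fix_success_rate_pct <= 100.0:
            raise ValidationError("success rate must lie in [0, 100]")


def summarize(attempts: Sequence[Attempt]) -> PerfSummary:
    """On-board style statistics from an attempt log.

    TTFF is the duration of the first successful cold-start attempt;
    the mean time to fix averages *all* successful attempt durations
    (cold and hot starts alike); the success rate counts successes over
    attempts; mean HDOP averages over successes that report one.
    """
    if not attempts:
        raise ValidationError("empty attempt log")
    succ = [a for a in attempts if a.outcome == "fix"]
    cold_succ = [a for a in succ if a.is_cold_start]
    hdops = [a.hdop for a in succ if a.hdop is not None]
    return PerfSummary(
        n_fixes=len(succ),
        ttff_s=cold_succ[0].duration_s if cold_succ else None,
        mean_ttf_s=float(np.mean([a.duration_s for a in succ])) if succ else None,
        mean_hdop=float(np.mean(hdops)) if hdops else None,
        fix_success_rate_pct=100.0 * len(succ) / len(attempts),
    )


def location_errors(
    track: pd.DataFrame, reference: pd.DataFrame, max_gap_s: float = 2.0
) -> tuple[pd.DataFrame, float | None, int]:
    """Great-circle distance of each track fix to the nearest-in-time
    reference fix.

    Both frames need ``utc`` (datetime64 or numeric seconds), ``lat``
    and ``lon`` columns.  Fixes without a reference within ``max_gap_s``
    are left unpaired.  Returns ``(pairs, mean_error_m, n_unpaired)``;
    the mean is None when nothing pairs (with a warning).
    """
    for name, df in (("track", track), ("reference", reference)):
        missing = {"utc", "lat", "lon"} - set(df.columns)
        if missing:
            raise ValidationError(f"{name} is missing columns {sorted(missing)}")
    t = track.sort_values("utc").reset_index(drop=True)
    r = reference.sort_values("utc").reset_index(drop=True)
    tol = (
        pd.Timedelta(seconds=max_gap_s)
        if pd.api.types.is_datetime64_any_dtype(t["utc"])
        else max_gap_s
    )
    pairs = pd.merge_asof(
        t,
        r.rename(columns={"lat": "ref_lat", "lon": "ref_lon"})[
            ["utc", "ref_lat", "ref_lon"]
        ],
        on="utc",
        direction="nearest",
        tolerance=tol,
    )
    unpaired = int(pairs["ref_lat"].isna().sum())
    paired = pairs.dropna(subset=["ref_lat"]).copy()
    if len(paired) == 0:
        warnings.warn("no track fixes could be paired with the reference")
        return paired.assign(error_m=pd.Series(dtype=float)), None, unpaired
    paired["error_m"] = haversine_m(
        paired["lat"].to_numpy(),
        paired["lon"].to_numpy(),
        paired["ref_lat"].to_numpy(),
        paired["ref_lon"].to_numpy(),
    )
    return paired, float(paired["error_m"].mean()), unpaired


def _round_ratio(value: float) -> float:
    """House rounding for efficiency ratios: one decimal below 100,
    nearest integer from 100 up."""
    return round(value, 1) if abs(value) < 100 else float(round(value))


def fixes_per_mah(n_fixes: int, capacity_mah: float) -> float:
    """Fixes per mAh of battery capacity (rounded per the house rule)."""
    if capacity_mah <= 0:
        raise ValidationError("capacity must be positive")
    return _round_ratio(n_fixes / capacity_mah)


def fixes_per_gram(n_fixes: int, mass_g: float) -> int:
    """Fixes per gram of deployed device mass, nearest integer."""
    if mass_g <= 0:
        raise ValidationError("mass must be positive")
    return int(round(n_fixes / mass_g))


def mode_comparison(
    groups: Mapping[str, Sequence[PerfSummary]],
    baseline: str,
    capacity_mah: float = 30.0,
) -> dict[str, dict[str, int]]:
    """Percentage change of each comparison metric relative to a baseline
    group.

    For every non-baseline group, computes
    ``100 * (mean_group - mean_baseline) / mean_baseline`` (rounded to
    integer percent) for the mean location error, the mean time to fix
    (only summaries reporting one contribute) and fixes per mAh
    (``n_fixes / capacity_mah``).  Identical groups give exactly 0.
    """
    if baseline not in groups:
        raise ValidationError(f"baseline group {baseline!r} not in groups")
    for label, members in groups.items():
        if not members:
            raise ValidationError(f"group {label!r} is empty")

    def metric_means(members: Sequence[PerfSummary]) -> dict[str, float | None]:
        errs = [s.mean_location_error_m for s in members if s.mean_location_error_m is not None]
        ttfs = [s.mean_ttf_s for s in members if s.mean_ttf_s is not None]
        fpm = [s.n_fixes / capacity_mah for s in members]
        return {
            "location_error_pct": float(np.mean(errs)) if errs else None,
            "time_to_fix_pct": float(np.mean(ttfs)) if ttfs else None,
            "fixes_per_mah_pct": float(np.mean(fpm)),
        }

    base = metric_means(groups[baseline])
    out: dict[str, dict[str, int]] = {}
    for label, members in groups.items():
        if label == baseline:
            continue
        means = metric_means(members)
        deltas: dict[str, int] = {}
        for metric, b in base.items():
            g = means[metric]
            if b is None or g is None or b == 0:
                continue
            deltas[metric] = int(round(100.0 * (g - b) / b))
        out[label] = deltas
    return out
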