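"""Synthetic animal tracks and degraded GPS observations.

Ground truth is a correlated random walk on the sphere: headings evolve
by von Mises turning angles (concentration = persistence), step lengths
are gamma-distributed around a mean speed, and metre-scale steps are
laid out in a local tangent plane (equirectangular projection, whose
error is far below 1 % at the sub-10 km scales of these walks).

Observations degrade the truth the way a receiver would: the truth is
subsampled at the tag's schedule, and isotropic Gaussian noise with
standard deviation ``sigma_base_m * HDOP`` per axis is added, with the
HDOP itself drawn from a gamma process.  Under that noise the radial
location error is Rayleigh distributed with mean ``sigma * sqrt(pi/2)``
— the closed form the statistical tests check against.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .errors import ValidationError
from .geofence import EARTH_RADIUS_M

_DEG = 180.0 / math.pi


class TrackParams(BaseModel):
    """Correlated-random-walk parameters for a ground-truth track."""

    n_steps: int = Field(3600, gt=0)
    step_interval_s: float = Field(1.0, gt=0)
    speed_mean_mps: float = Field(1.5, ge=0)
    #: von Mises concentration of turning angles; 0 = uncorrelated turning,
    #: large values approach straight-line travel.
    turning_concentration: float = Field(5.0, ge=0)
    #: gamma shape of per-step speeds (larger = steadier pace)
    speed_shape: float = Field(4.0, gt=0)
    start_lat: float = Field(47.69, ge=-90, le=90)
    start_lon: float = Field(9.19, ge=-180, lt=180)
    start_utc_s: int = Field(0, ge=0)
    seed: int = 0


class NoiseModel(BaseModel):
    """GPS degradation: HDOP-scaled isotropic position noise."""

    #: per-axis error scale at HDOP 1, metres
    sigma_base_m: float = Field(8.0, ge=0)
    hdop_mean: float = Field(1.8, gt=0)
    hdop_shape: float = Field(10.0, gt=0)
    #: when set, every observation gets exactly this HDOP (no draw)
    hdop_fixed: Optional[float] = Field(None, gt=0)
    seed: int = 0


def generate_track(params: TrackParams) -> pd.DataFrame:
    """Simulate a correlated random walk; returns utc/lat/lon columns.

    Reproducible for a fixed seed.  Zero mean speed gives a stationary
    track; infinite turning concentration a straight line.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_steps
    if params.turning_concentration >= 1e9 or math.isinf(params.turning_concentration):
        turns = np.zeros(n)
    elif params.turning_concentration == 0:
        turns = rng.uniform(-math.pi, math.pi, size=n)
    else:
        turns = rng.vonmises(0.0, params.turning_concentration, size=n)
    heading = rng.uniform(0.0, 2.0 * math.pi) + np.cumsum(turns)
    if params.speed_mean_mps > 0:
        speeds = rng.gamma(
            params.speed_shape,
            params.speed_mean_mps / params.speed_shape,
            size=n,
        )
    else:
        speeds = np.zeros(n)
    steps = speeds * params.step_interval_s
    de = np.concatenate([[0.0], np.cumsum(steps * np.cos(heading))])  # east, m
    dn = np.concatenate([[0.0], np.cumsum(steps * np.sin(heading))])  # north, m
    lat = params.start_lat + dn / EARTH_RADIUS_M * _DEG
    lon = params.start_lon + de / (
        EARTH_RADIUS_M * math.cos(math.radians(params.start_lat))
    ) * _DEG
    if np.any(np.abs(lat) > 90):
        raise ValidationError("track left the supported latitude range")
    utc = params.start_utc_s + np.arange(n + 1) * params.step_interval_s
    return pd.DataFrame({"utc": utc, "lat": lat, "lon": lon})


def _schedule_times(schedule, t0: float, t1: float) -> np.ndarray:
    """Sampling instants of a tag schedule across the half-open [t0, t1)."""
    if schedule.burst_len_s > 0:
        period = schedule.burst_len_s + schedule.burst_gap_s
        starts = np.arange(t0, t1, period)
        offs = np.arange(int(schedule.burst_len_s))
        times = (starts[:, None] + offs[None, :]).ravel()
        return times[times < t1]
    return np.arange(t0, t1, schedule.interval_s)


def degrade_to_observations(
    truth: pd.DataFrame, noise: NoiseModel, schedule
) -> pd.DataFrame:
    """Subsample a truth track per the tag schedule and add GPS noise.

    ``schedule`` is a :class:`~microgps.simulate.TagConfig` (or any
    object with ``interval_s``/``burst_len_s``/``burst_gap_s``).  The
    truth must cover the schedule span; positions are interpolated
    linearly between truth samples.  Returns utc/lat/lon/hdop columns.
    """
    if len(truth) < 2:
        raise ValidationError("truth track needs at least two samples")
    t = np.asarray(truth["utc"], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValidationError("truth timestamps must be strictly increasing")
    times = _schedule_times(schedule, t[0], t[-1])
    if len(times) == 0:
        raise ValidationError("schedule produces no samples within the truth span")
    lat = np.interp(times, t, np.asarray(truth["lat"], dtype=float))
    lon = np.interp(times, t, np.asarray(truth["lon"], dtype=float))
    rng = np.random.default_rng(noise.seed)
    if noise.hdop_fixed is not None:
        hdop = np.full(len(times), noise.hdop_fixed)
    else:
        hdop = rng.gamma(noise.hdop_shape, noise.hdop_mean / noise.hdop_shape, len(times))
    sigma = noise.sigma_base_m * hdop
    de = rng.normal(0.0, 1.0, len(times)) * sigma
    dn = rng.normal(0.0, 1.0, len(times)) * sigma
    lat_out = lat + dn / EARTH_RADIUS_M * _DEG
    lon_out = lon + de / (EARTH_RADIUS_M * np.cos(np.radians(lat))) * _DEG
    return pd.DataFrame(
        {"utc": times, "lat": lat_out, "lon": lon_out, "hdop": hdop}
    )
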