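"""Great-circle distance and the self-configuring geofence filter.

The logger can memorise the first fix after activation as its *home*
location and suppress storage of every later fix that falls within a
configurable radius (default 300 m) of home, instead triggering a
hibernation hold (default 600 s).  Distances are great-circle
(haversine) on a sphere of mean radius 6,371 km; points at exactly the
radius count as inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .codec import GpsFix
from .errors import ValidationError

#: Mean Earth radius in metres.
EARTH_RADIUS_M = 6_371_000.0


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValidationError("coordinates out of range")


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres between two points (or arrays).

    Symmetric and non-negative; identical points give exactly 0.
    """
    _check_coords(lat1, lon1)
    _check_coords(lat2, lon2)
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    h = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if np.isscalar(lat1) or np.ndim(d) == 0 else d


@dataclass
class GeofenceEvent:
    """A suppression: the fix at ``utc`` was inside the fence."""

    utc: int
    distance_m: float
    hold_s: float


@dataclass
class GeofenceState:
    """Mutable filter state: home location, radius, hold, counters."""

    home: GpsFix | None = None
    radius_m: float = 300.0
    hold_s: float = 600.0
    suppressed_count: int = 0

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValidationError("geofence radius must be positive")
        if self.hold_s < 0:
            raise ValidationError("geofence hold must be non-negative")


def geofence_filter(
    stream: Iterable[GpsFix], state: GeofenceState | None = None
) -> tuple[list[GpsFix], list[GeofenceEvent], GeofenceState]:
    """Filter a time-ordered fix stream against a home-centred fence.

    The first processed fix sets ``state.home`` and is stored.  Later
    fixes at a distance ``<= radius_m`` from home are suppressed and
    emit a :class:`GeofenceEvent` carrying the hibernation hold; fixes
    beyond the radius are stored.  ``stored + suppressed`` always equals
    the input count.
    """
    state = state or GeofenceState()
    stored: list[GpsFix] = []
    events: list[GeofenceEvent] = []
    last_utc: int | None = None
    for fix in stream:
        if last_utc is not None and fix.utc < last_utc:
            raise ValidationError(
                f"stream not time-ordered at utc={fix.utc} (previous {last_utc})"
            )
        last_utc = fix.utc
        if state.home is None:
            state.home = fix
            stored.append(fix)
            continue
        d = haversine_m(state.home.lat, state.home.lon, fix.lat, fix.lon)
        if d <= state.radius_m:  # boundary convention: exactly on the radius is inside
            state.suppressed_count += 1
            events.append(GeofenceEvent(utc=fix.utc, distance_m=d, hold_s=state.hold_s))
        else:
            stored.append(fix)
    return stored, events, state
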