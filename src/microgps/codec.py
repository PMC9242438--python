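"""10-byte fix records and the EEPROM memory image.

The logger persists each GPS fix as a fixed-width 10-octet record on a
128 kByte EEPROM, which holds 13,107 records.  The layout used here is a
documented convention of this toolkit:

======  =======================================================
octets  content
======  =======================================================
0–3     unsigned seconds since the epoch, big-endian
4–6     latitude, linear code ``round((lat+90)/180 * (2^24-1))``
7–9     longitude, linear code ``round((lon+180)/360 * (2^24-1))``
======  =======================================================

The 24-bit linear quantisation gives a coordinate step of
``180/(2^24-1) ≈ 1.07e-5`` degrees latitude (about 1.2 m), so decoding
an encoded fix reproduces it to well under metre scale.  The epoch is
2000-01-01T00:00:00 UTC by default (GPS-module friendly; four octets
cover several decades) and is configurable wherever timestamps are
converted.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone

from .errors import FormatError, MemoryFullError, ValidationError

#: Default epoch for the 4-octet timestamp field.
EPOCH = datetime(2000, 1, 1, tzinfo=timezone.utc)

RECORD_SIZE = 10
EEPROM_BYTES = 131072

_Q_STEPS = (1 << 24) - 1  # quantisation codes per coordinate
LAT_STEP_DEG = 180.0 / _Q_STEPS
LON_STEP_DEG = 360.0 / _Q_STEPS


@dataclass(frozen=True)
class GpsFix:
    """One position estimate.

    Parameters
    ----------
    utc : int
        Seconds since :data:`EPOCH`; non-negative.
    lat, lon : float
        Decimal degrees, ``lat`` in [-90, +90], ``lon`` in [-180, +180).
    hdop : float, optional
        Horizontal dilution of precision; not stored in the 10-byte
        record.
    """

    utc: int
    lat: float
    lon: float
    hdop: float | None = None

    def __post_init__(self) -> None:
        if self.utc < 0:
            raise ValidationError(f"negative timestamp: {self.utc}")
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"latitude out of range: {self.lat}")
        if not -180.0 <= self.lon < 180.0:
            raise ValidationError(f"longitude out of range: {self.lon}")
        if self.hdop is not None and self.hdop < 0:
            raise ValidationError(f"negative HDOP: {self.hdop}")


def encode_fix(fix: GpsFix) -> bytes:
    """Encode a fix as a 10-octet record (timestamp, lat code, lon code)."""
    if fix.utc > 0xFFFFFFFF:
        raise ValidationError(f"timestamp does not fit in 4 octets: {fix.utc}")
    lat_code = round((fix.lat + 90.0) / 180.0 * _Q_STEPS)
    lon_code = round((fix.lon + 180.0) / 360.0 * _Q_STEPS)
    return (
        fix.utc.to_bytes(4, "big")
        + lat_code.to_bytes(3, "big")
        + lon_code.to_bytes(3, "big")
    )


def decode_fix(record: bytes) -> GpsFix:
    """Decode a 10-octet record back to a fix (within quantisation error)."""
    if len(record) != RECORD_SIZE:
        raise FormatError(f"record must be {RECORD_SIZE} octets, got {len(record)}")
    utc = int.from_bytes(record[0:4], "big")
    lat = int.from_bytes(record[4:7], "big") / _Q_STEPS * 180.0 - 90.0
    lon = int.from_bytes(record[7:10], "big") / _Q_STEPS * 360.0 - 180.0
    # the top longitude code decodes to +180.0 exactly; fold it into range
    if lon >= 180.0:
        lon = 180.0 - LON_STEP_DEG / 2
    return GpsFix(utc=utc, lat=lat, lon=lon)


def eeprom_capacity(memory_bytes: int = EEPROM_BYTES, record_size: int = RECORD_SIZE) -> int:
    """Number of whole records a memory of ``memory_bytes`` can hold."""
    if memory_bytes <= 0 or record_size <= 0:
        raise ValidationError("memory size and record size must be positive")
    return memory_bytes // record_size


class MemoryImage:
    """The tag's persistent store: concatenated 10-octet records.

    Records are kept in recording order; ``used_bytes`` is always
    ``10 * len(records)`` and never exceeds ``capacity_bytes``.
    """

    def __init__(self, capacity_bytes: int = EEPROM_BYTES):
        if capacity_bytes <= 0:
            raise ValidationError("capacity must be positive")
        self.capacity_bytes = capacity_bytes
        self._buf = bytearray()

    @property
    def used_bytes(self) -> int:
        return len(self._buf)

    @property
    def n_records(self) -> int:
        return len(self._buf) // RECORD_SIZE

    @property
    def capacity_records(self) -> int:
        return eeprom_capacity(self.capacity_bytes, RECORD_SIZE)

    @property
    def full(self) -> bool:
        return self.n_records >= self.capacity_records

    def append_fix(self, fix: GpsFix) -> "MemoryImage":
        """Append one fix; raises :class:`MemoryFullError` when full."""
        if self.full:
            raise MemoryFullError(
                f"image full at {self.n_records} records ({self.used_bytes} bytes)"
            )
        self._buf += encode_fix(fix)
        return self

    def records(self) -> list[bytes]:
        return [
            bytes(self._buf[i : i + RECORD_SIZE])
            for i in range(0, len(self._buf), RECORD_SIZE)
        ]

    def fixes(self) -> list[GpsFix]:
        return [decode_fix(r) for r in self.records()]

    def tobytes(self) -> bytes:
        return bytes(self._buf)

    @classmethod
    def frombytes(cls, raw: bytes, capacity_bytes: int = EEPROM_BYTES) -> "MemoryImage":
        if len(raw) % RECORD_SIZE != 0:
            raise FormatError(
                f"image size {len(raw)} is not a multiple of {RECORD_SIZE}"
            )
        if len(raw) > capacity_bytes:
            raise FormatError("image larger than declared capacity")
        img = cls(capacity_bytes)
        img._buf = bytearray(raw)
        return img


def utc_seconds(dt: datetime, epoch: datetime = EPOCH) -> int:
    """Seconds since the codec epoch for a timezone-aware datetime."""
    if dt.tzinfo is None:
        raise ValidationError("timestamp must be timezone-aware")
    return int(round((dt - epoch).total_seconds()))


def utc_datetime(seconds: int | float, epoch: datetime = EPOCH) -> datetime:
    """Inverse of :func:`utc_seconds`."""
    from datetime import timedelta

    return epoch + timedelta(seconds=float(seconds))
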