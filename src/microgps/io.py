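"""Readers and writers for the toolkit's on-disk formats.

Three formats are supported: the CSV fix table (header
``utc_iso8601,lat_deg,lon_deg,hdop``; coordinates at 6 decimals,
~0.11 m, finer than the binary codec's quantisation), GPX 1.1 for map
inspection, and the raw binary memory image of concatenated 10-octet
records (no header).  Timestamps are always UTC ISO-8601 with a ``Z``
suffix; epoch conversions go through :mod:`microgps.codec`.

The in-memory fix table is a pandas DataFrame with columns ``utc``
(timezone-aware datetimes), ``lat``, ``lon`` and ``hdop`` (NaN where
absent).
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .codec import EPOCH, GpsFix, MemoryImage, utc_datetime, utc_seconds
from .errors import FormatError, ValidationError

CSV_COLUMNS = ["utc_iso8601", "lat_deg", "lon_deg", "hdop"]
GPX_NS = "http://www.topografix.com/GPX/1/1"


def fixes_to_frame(fixes: list[GpsFix], epoch: datetime = EPOCH) -> pd.DataFrame:
    """Fix objects → fix-table DataFrame."""
    return pd.DataFrame(
        {
            "utc": [utc_datetime(f.utc, epoch) for f in fixes],
            "lat": [f.lat for f in fixes],
            "lon": [f.lon for f in fixes],
            "hdop": [np.nan if f.hdop is None else f.hdop for f in fixes],
        }
    )


def frame_to_fixes(table: pd.DataFrame, epoch: datetime = EPOCH) -> list[GpsFix]:
    """Fix-table DataFrame → fix objects (row order preserved)."""
    out = []
    for row in table.itertuples(index=False):
        hdop = getattr(row, "hdop", np.nan)
        out.append(
            GpsFix(
                utc=utc_seconds(_as_utc(row.utc), epoch),
                lat=float(row.lat),
                lon=float(row.lon),
                hdop=None if pd.isna(hdop) else float(hdop),
            )
        )
    return out


def _as_utc(value) -> datetime:
    ts = pd.Timestamp(value)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    return ts.to_pydatetime()


def read_csv(path: str | Path) -> pd.DataFrame:
    """Read a fix table, validating every row.

    Malformed rows raise a :class:`ValidationError` naming the line
    number; an empty file returns an empty table with a warning.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() == "":
        warnings.warn(f"{path}: empty fix table")
        return pd.DataFrame(columns=["utc", "lat", "lon", "hdop"])
    lines = text.strip().splitlines()
    header = [h.strip() for h in lines[0].split(",")]
    if header != CSV_COLUMNS:
        raise ValidationError(
            f"{path}:1: expected header {','.join(CSV_COLUMNS)!r}, got {lines[0]!r}"
        )
    utcs, lats, lons, hdops = [], [], [], []
    prev: pd.Timestamp | None = None
    for lineno, line in enumerate(lines[1:], start=2):
        if line.strip() == "":
            continue
        parts = line.split(",")
        if len(parts) != 4:
            raise ValidationError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
        try:
            ts = pd.Timestamp(parts[0])
            if ts.tzinfo is None:
                ts = ts.tz_localize("UTC")
            lat = float(parts[1])
            lon = float(parts[2])
            hdop = float(parts[3]) if parts[3].strip() != "" else np.nan
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
        if not -90.0 <= lat <= 90.0:
            raise ValidationError(f"{path}:{lineno}: latitude out of range: {lat}")
        if not -180.0 <= lon < 180.0:
            raise ValidationError(f"{path}:{lineno}: longitude out of range: {lon}")
        if not np.isnan(hdop) and hdop < 0:
            raise ValidationError(f"{path}:{lineno}: negative HDOP: {hdop}")
        if prev is not None and ts < prev:
            raise ValidationError(f"{path}:{lineno}: timestamps decrease at {parts[0]}")
        prev = ts
        utcs.append(ts)
        lats.append(lat)
        lons.append(lon)
        hdops.append(hdop)
    return pd.DataFrame({"utc": utcs, "lat": lats, "lon": lons, "hdop": hdops})


def write_csv(path: str | Path, table: pd.DataFrame) -> None:
    """Write a fix table (coordinates at 6 decimals, times ISO-8601 Z)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(",".join(CSV_COLUMNS) + "\n")
        for row in table.itertuples(index=False):
            hdop = getattr(row, "hdop", np.nan)
            hdop_s = "" if pd.isna(hdop) else f"{float(hdop):g}"
            fh.write(
                f"{_iso(row.utc)},{float(row.lat):.6f},{float(row.lon):.6f},{hdop_s}\n"
            )


def _iso(value) -> str:
    dt = _as_utc(value).astimezone(timezone.utc)
    return dt.strftime("%Y-%m-%dT%H:%M:%SZ")


def write_gpx(path: str | Path, table: pd.DataFrame, name: str = "track") -> None:
    """Write a GPX 1.1 document: one track, one segment, one trackpoint
    per fix (with ``time`` and, where present, ``hdop`` elements)."""
    ET.register_namespace("", GPX_NS)
    gpx = ET.Element(
        f"{{{GPX_NS}}}gpx", attrib={"version": "1.1", "creator": "microgps"}
    )
    trk = ET.SubElement(gpx, f"{{{GPX_NS}}}trk")
    ET.SubElement(trk, f"{{{GPX_NS}}}name").text = name
    seg = ET.SubElement(trk, f"{{{GPX_NS}}}trkseg")
    for row in table.itertuples(index=False):
        pt = ET.SubElement(
            seg,
            f"{{{GPX_NS}}}trkpt",
            attrib={"lat": f"{float(row.lat):.6f}", "lon": f"{float(row.lon):.6f}"},
        )
        ET.SubElement(pt, f"{{{GPX_NS}}}time").text = _iso(row.utc)
        hdop = getattr(row, "hdop", np.nan)
        if not pd.isna(hdop):
            ET.SubElement(pt, f"{{{GPX_NS}}}hdop").text = f"{float(hdop):g}"
    tree = ET.ElementTree(gpx)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")


def encode_image(table: pd.DataFrame, path: str | Path, epoch: datetime = EPOCH) -> None:
    """Write a fix table as a raw binary memory image."""
    img = MemoryImage(capacity_bytes=max(10 * len(table), 10))
    for fix in frame_to_fixes(table, epoch):
        img.append_fix(fix)
    Path(path).write_bytes(img.tobytes())


def decode_image(path: str | Path, epoch: datetime = EPOCH) -> pd.DataFrame:
    """Read a raw binary memory image back into a fix table.

    The file size must be a multiple of the 10-octet record size.
    """
    raw = Path(path).read_bytes()
    if len(raw) % 10 != 0:
        raise FormatError(f"{path}: size {len(raw)} is not a multiple of 10")
    img = MemoryImage.frombytes(raw, capacity_bytes=max(len(raw), 10))
    return fixes_to_frame(img.fixes(), epoch)
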