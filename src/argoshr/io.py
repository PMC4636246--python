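"""Readers and writers: fix tables, GPX tracks, result tables, GeoJSON, manifests.

The canonical fix format is comma-separated text with a header
``id,timestamp,lon,lat,lc`` — timestamps ISO 8601 UTC, ``lc`` empty for GPS
fixes. GPX is accepted read-only as a convenience for GPS tracks.
"""

from __future__ import annotations

import json
import logging
import warnings
import xml.etree.ElementTree as ET
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geo import CRS, Fix, Track, LOCATION_CLASSES
from .homerange import HomeRange

logger = logging.getLogger(__name__)

FIX_COLUMNS = ["id", "timestamp", "lon", "lat", "lc"]


def _parse_timestamp(raw: str) -> float:
    """ISO 8601 -> epoch seconds. A timestamp without an explicit zone is
    assumed UTC, with a warning."""
    s = str(raw).strip()
    dt = datetime.fromisoformat(s.replace("Z", "+00:00"))
    if dt.tzinfo is None:
        warnings.warn(f"timestamp {s!r} has no zone marker; assuming UTC", stacklevel=3)
        dt = dt.replace(tzinfo=timezone.utc)
    return dt.timestamp()


def _format_timestamp(t: float) -> str:
    return datetime.fromtimestamp(t, tz=timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


def read_fixes(path: str | Path, kind: str) -> list[Track]:
    """Read a fix table and group it into per-id tracks sorted by time.

    *kind* is ``"argos"`` or ``"gps"``. Malformed rows are rejected with
    their line numbers logged; a duplicated (id, timestamp) pair is an error.
    """
    if kind not in ("argos", "gps"):
        raise ValueError(f"kind must be 'argos' or 'gps', got {kind!r}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in FIX_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    fixes: list[Fix] = []
    bad: list[int] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            lc = row.get("lc", "").strip() or None
            if kind == "argos" and (lc is None or lc not in LOCATION_CLASSES):
                raise ValueError(f"invalid location class {lc!r}")
            fixes.append(
                Fix(
                    id=str(row["id"]),
                    t=_parse_timestamp(row["timestamp"]),
                    lon=float(row["lon"]),
                    lat=float(row["lat"]),
                    lc=lc if kind == "argos" else None,
                    source=kind,
                )
            )
        except (ValueError, KeyError) as e:
            bad.append(line)
            logger.warning("%s line %d: rejected (%s)", path, line, e)
    if bad:
        logger.warning("%s: rejected %d malformed row(s)", path, len(bad))

    seen: set[tuple[str, float]] = set()
    for f in fixes:
        key = (f.id, f.t)
        if key in seen:
            raise ValueError(
                f"{path}: duplicate (id, timestamp) pair ({f.id!r}, {_format_timestamp(f.t)})"
            )
        seen.add(key)

    tracks: dict[str, list[Fix]] = {}
    for f in fixes:
        tracks.setdefault(f.id, []).append(f)
    return [
        Track(tid, sorted(fs, key=lambda f: f.t)) for tid, fs in tracks.items()
    ]


def write_fixes(tracks: Iterable[Track], path: str | Path) -> None:
    """Write tracks to the canonical fix table."""
    rows = []
    for trk in tracks:
        for f in trk.fixes:
            rows.append(
                {
                    "id": f.id,
                    "timestamp": _format_timestamp(f.t),
                    "lon": f"{f.lon:.8f}",
                    "lat": f"{f.lat:.8f}",
                    "lc": f.lc or "",
                }
            )
    pd.DataFrame(rows, columns=FIX_COLUMNS).to_csv(path, index=False)


def read_gpx(path: str | Path, session_id: str | None = None) -> Track:
    """Read the track points of a GPX file as one GPS track."""
    ns = {"gpx": "http://www.topografix.com/GPX/1/1"}
    root = ET.parse(str(path)).getroot()
    pts = root.findall(".//gpx:trkpt", ns) or root.findall(".//trkpt")
    fixes = []
    sid = session_id or Path(path).stem
    for pt in pts:
        time_el = pt.find("gpx:time", ns)
        if time_el is None:
            time_el = pt.find("time")
        if time_el is None:
            continue
        fixes.append(
            Fix(
                id=sid,
                t=_parse_timestamp(time_el.text),
                lon=float(pt.attrib["lon"]),
                lat=float(pt.attrib["lat"]),
                source="gps",
            )
        )
    return Track(sid, sorted(fixes, key=lambda f: f.t))


# ---------------------------------------------------------------------------
# results

def homerange_to_geojson(hr: HomeRange, crs: CRS | None = None) -> dict:
    """A home range as a GeoJSON Feature in planar coordinates, with the
    projection origin recorded as properties."""
    props: dict = {"method": hr.method, "area_km2": round(hr.area / 1e6, 3)}
    if crs is not None:
        props["crs_origin_lon"] = crs.lon0
        props["crs_origin_lat"] = crs.lat0
    if hr.method == "mcp95":
        ring = np.vstack([hr.vertices, hr.vertices[:1]])
        geometry = {"type": "Polygon", "coordinates": [ring.tolist()]}
    else:
        from shapely.geometry import box, mapping
        from shapely.ops import unary_union

        ud = hr.grid
        cells = [
            box(ud.x0 + j * ud.cell, ud.y0 + i * ud.cell,
                ud.x0 + (j + 1) * ud.cell, ud.y0 + (i + 1) * ud.cell)
            for i, j in hr.cells
        ]
        geometry = json.loads(json.dumps(mapping(unary_union(cells))))
    return {"type": "Feature", "geometry": geometry, "properties": props}


def write_results(
    metrics: pd.DataFrame,
    outdir: str | Path,
    polygons: Mapping[str, tuple[HomeRange, CRS | None]] | None = None,
    manifest: Mapping | None = None,
    name: str = "metrics",
) -> dict[str, Path]:
    """Write a tidy metrics table, optional GeoJSON geometries, and a JSON run
    manifest under *outdir*. Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    table = outdir / f"{name}.csv"
    metrics.to_csv(table, index=False)
    written["metrics"] = table

    if polygons:
        features = [homerange_to_geojson(hr, crs) for hr, crs in polygons.values()]
        for key, feat in zip(polygons, features):
            feat["properties"]["name"] = key
        gj = outdir / f"{name}.geojson"
        gj.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
        written["geojson"] = gj

    if manifest is not None:
        mf = outdir / f"{name}_manifest.json"
        mf.write_text(json.dumps(dict(manifest), indent=2, sort_keys=True, default=str))
        written["manifest"] = mf
    return written
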