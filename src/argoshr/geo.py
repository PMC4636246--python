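"""Coordinates, tracks, GPS reference construction and location-error measurement.

All planar work happens in a local azimuthal-equidistant projection on a
spherical earth (R = 6 371 000 m), centered on a per-session origin. Study
extents are a few kilometres, where the distortion of this frame is far
below the measurement error of satellite telemetry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

#: Argos location classes, best to worst. Z flags an invalid location.
LOCATION_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")


@dataclass(frozen=True)
class Fix:
    """One timestamped position.

    Parameters
    ----------
    id : str
        Platform / session identifier.
    t : float
        UTC timestamp, seconds since the Unix epoch.
    lon, lat : float
        Geographic coordinates in decimal degrees.
    lc : str or None
        Argos location class in ``{3, 2, 1, 0, A, B, Z}``; ``None`` for GPS.
    source : str
        ``"gps"`` or ``"argos"``. A location class is present iff the fix
        is an Argos fix.
    """

    id: str
    t: float
    lon: float
    lat: float
    lc: str | None = None
    source: str = "gps"

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if self.source not in ("gps", "argos"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "argos":
            if self.lc is None or str(self.lc) not in LOCATION_CLASSES:
                raise ValueError(f"argos fix requires a location class, got {self.lc!r}")
        elif self.lc is not None:
            raise ValueError("gps fix must not carry a location class")


@dataclass
class Track:
    """An ordered sequence of fixes from a single source.

    Timestamps must be strictly increasing and every fix must share one
    source (all GPS or all Argos).
    """

    session_id: str
    fixes: list[Fix] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fixes:
            sources = {f.source for f in self.fixes}
            if len(sources) > 1:
                raise ValueError(f"track {self.session_id!r} mixes sources {sources}")
            t = self.times
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"track {self.session_id!r} timestamps not strictly increasing")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def source(self) -> str:
        if not self.fixes:
            raise ValueError("empty track has no source")
        return self.fixes[0].source

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t for f in self.fixes], dtype=float)

    @property
    def lonlat(self) -> np.ndarray:
        return np.array([(f.lon, f.lat) for f in self.fixes], dtype=float)


@dataclass(frozen=True)
class CRS:
    """Descriptor of a local azimuthal-equidistant frame: its origin."""

    lon0: float
    lat0: float


@dataclass(frozen=True)
class PlanarPoint:
    """A point in a local planar frame: metres east (x) and north (y) of the origin."""

    x: float
    y: float
    crs: CRS


@dataclass(frozen=True)
class ErrorRecord:
    """An Argos fix paired with its reference position and planar error components.

    ``err_x`` / ``err_y`` are signed east/north offsets (Argos minus
    reference); ``err_total`` is their Euclidean norm.
    """

    argos: Fix
    ref: PlanarPoint
    err_total: float
    err_x: float
    err_y: float


# ---------------------------------------------------------------------------
# projection

def _check_domain(lon: np.ndarray, lat: np.ndarray, crs: CRS) -> None:
    ang = _angular_distance_deg(lon, lat, crs)
    if np.any(ang > 5.0):
        raise ValueError(
            f"point(s) up to {float(np.max(ang)):.2f} degrees from projection origin; "
            "local projection is only valid within 5 degrees"
        )


def _angular_distance_deg(lon, lat, crs: CRS):
    lam, phi = np.radians(lon), np.radians(lat)
    lam0, phi0 = math.radians(crs.lon0), math.radians(crs.lat0)
    cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    return np.degrees(np.arccos(np.clip(cosc, -1.0, 1.0)))


def project_lonlat(lon, lat, crs: CRS) -> tuple[np.ndarray, np.ndarray]:
    """Forward azimuthal-equidistant projection (spherical). Vectorized."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    _check_domain(lon, lat, crs)
    lam, phi = np.radians(lon), np.radians(lat)
    lam0, phi0 = math.radians(crs.lon0), math.radians(crs.lat0)
    cosc = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    c = np.arccos(np.clip(cosc, -1.0, 1.0))
    # k = c / sin(c), -> 1 as c -> 0
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
    x = EARTH_RADIUS_M * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_M * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


def unproject_xy(x, y, crs: CRS) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`project_lonlat`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho = np.hypot(x, y)
    c = rho / EARTH_RADIUS_M
    lam0, phi0 = math.radians(crs.lon0), math.radians(crs.lat0)
    safe_rho = np.where(rho > 1e-12, rho, 1.0)
    phi = np.arcsin(
        np.cos(c) * math.sin(phi0) + np.where(rho > 1e-12, y * np.sin(c) * math.cos(phi0) / safe_rho, 0.0)
    )
    lam = lam0 + np.arctan2(
        x * np.sin(c),
        safe_rho * np.cos(c) * math.cos(phi0) - y * np.sin(c) * math.sin(phi0),
    )
    lam = np.where(rho > 1e-12, lam, lam0)
    phi = np.where(rho > 1e-12, phi, phi0)
    return np.degrees(lam), np.degrees(phi)


def project(fix: Fix, origin: tuple[float, float] | CRS) -> PlanarPoint:
    """Project a fix into the local planar frame centered at *origin* (lon, lat)."""
    crs = origin if isinstance(origin, CRS) else CRS(*origin)
    x, y = project_lonlat(fix.lon, fix.lat, crs)
    return PlanarPoint(float(x), float(y), crs)


def track_crs(track: Track) -> CRS:
    """Local frame centered on the track's mean coordinate (the session centroid)."""
    ll = track.lonlat
    if ll.size == 0:
        raise ValueError("empty track")
    return CRS(float(ll[:, 0].mean()), float(ll[:, 1].mean()))


def project_track(track: Track, crs: CRS) -> np.ndarray:
    """Planar (n, 2) coordinates of a track's fixes in *crs*."""
    ll = track.lonlat
    x, y = project_lonlat(ll[:, 0], ll[:, 1], crs)
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# references

def static_reference(gps: Track, crs: CRS | None = None) -> PlanarPoint:
    """Reference position of a static test site: the mean of all its GPS fixes."""
    if not gps.fixes:
        raise ValueError("cannot build a static reference from an empty track")
    if gps.source != "gps":
        raise ValueError("static reference requires a GPS track")
    crs = crs or track_crs(gps)
    xy = project_track(gps, crs)
    return PlanarPoint(float(xy[:, 0].mean()), float(xy[:, 1].mean()), crs)


def interpolate_reference(
    gps: Track, t: float, crs: CRS | None = None, max_gap: float = 600.0
) -> PlanarPoint | None:
    """Reference position at time *t*, linearly interpolated between the bracketing
    GPS fixes.

    Returns ``None`` when *t* falls outside the track's time span, or when the
    bracketing gap is *max_gap* seconds or longer (strict ``< max_gap`` rule:
    Doppler timestamps are satellite-pass averages, so wide GPS gaps make the
    interpolated truth unreliable). Exact matches with a GPS fix time return
    that fix's position regardless of neighbouring gaps.
    """
    if not gps.fixes:
        raise ValueError("empty GPS track")
    if gps.source != "gps":
        raise ValueError("interpolation reference requires a GPS track")
    times = gps.times
    crs = crs or track_crs(gps)
    if t < times[0] or t > times[-1]:
        return None
    j = int(np.searchsorted(times, t, side="left"))
    if times[j] == t:
        return project(gps.fixes[j], crs)
    i = j - 1
    t1, t2 = times[i], times[j]
    if (t2 - t1) >= max_gap:
        return None
    frac = (t - t1) / (t2 - t1)
    p1 = project(gps.fixes[i], crs)
    p2 = project(gps.fixes[j], crs)
    return PlanarPoint(p1.x + frac * (p2.x - p1.x), p1.y + frac * (p2.y - p1.y), crs)


def location_error(argos: Fix, ref: PlanarPoint) -> ErrorRecord:
    """Planar error of an Argos fix against its reference position.

    The Argos fix is projected into the reference's frame; the error is the
    signed east/north offset and its Euclidean norm.
    """
    p = project(argos, ref.crs)
    dx = p.x - ref.x
    dy = p.y - ref.y
    return ErrorRecord(argos=argos, ref=ref, err_total=float(np.hypot(dx, dy)), err_x=dx, err_y=dy)


def match_mobile_session(
    argos: Track, gps: Track, crs: CRS | None = None, max_gap: float = 600.0
) -> list[ErrorRecord]:
    """Pair every Argos fix of a mobile session with its interpolated GPS reference.

    Fixes outside the GPS time span or astride a too-wide GPS gap are dropped;
    the count of dropped fixes is logged.
    """
    crs = crs or track_crs(gps)
    records: list[ErrorRecord] = []
    dropped = 0
    for fx in argos.fixes:
        ref = interpolate_reference(gps, fx.t, crs=crs, max_gap=max_gap)
        if ref is None:
            dropped += 1
            continue
        records.append(location_error(fx, ref))
    if dropped:
        logger.info(
            "session %s: dropped %d/%d argos fixes without a valid GPS reference",
            argos.session_id, dropped, len(argos.fixes),
        )
    return records
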