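"""Destructive filtering of Argos tracks.

Two families: location-class retention (keep only the best classes) and a
speed filter that drops fixes implying implausible travel speeds. Both
return subsequences of the input track; neither modifies fixes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .geo import CRS, Track, project_track, track_crs

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeedFilterConfig:
    """Parameters of the speed filter.

    A fix is retained when the speed from the last retained fix is below
    ``cruise_speed``, or below ``max_speed`` provided the elapsed time is
    shorter than ``max_accel_duration`` (a burst the animal can sustain only
    briefly). Defaults are tuned for a walking human in open tundra.
    """

    cruise_speed: float = 6.0  # km/h
    max_speed: float = 8.0  # km/h
    max_accel_duration: float = 20.0  # minutes

    def __post_init__(self) -> None:
        if not 0 < self.cruise_speed <= self.max_speed:
            raise ValueError("need 0 < cruise_speed <= max_speed")
        if self.max_accel_duration <= 0:
            raise ValueError("max_accel_duration must be positive")


def lc_filter(track: Track, keep: Iterable[str]) -> Track:
    """Keep only fixes whose location class is in *keep*; invalid (LCZ) fixes
    are always removed, with a logged count."""
    if track.fixes and track.source != "argos":
        raise ValueError("lc_filter applies to Argos tracks")
    keep = {str(k) for k in keep}
    n_z = sum(1 for f in track.fixes if f.lc == "Z")
    if n_z:
        logger.info("track %s: removed %d invalid (LCZ) fixes", track.session_id, n_z)
    kept = [f for f in track.fixes if f.lc != "Z" and f.lc in keep]
    return Track(track.session_id, kept)


def lc3(track: Track) -> Track:
    return lc_filter(track, {"3"})


def lc32(track: Track) -> Track:
    return lc_filter(track, {"3", "2"})


def lc321(track: Track) -> Track:
    return lc_filter(track, {"3", "2", "1"})


def speed_filter(
    track: Track, cfg: SpeedFilterConfig = SpeedFilterConfig(), crs: CRS | None = None
) -> Track:
    """Sequentially drop fixes implying implausible speeds.

    The first fix is always retained (there is no previous location to judge
    it against). Each later fix is compared to the last *retained* fix: with
    planar distance d (m) and elapsed time dt (s), the speed v = 3.6 d/dt
    (km/h) must satisfy ``v < cruise_speed``, or ``v < max_speed`` with
    ``dt < max_accel_duration``; otherwise the later fix of the pair is
    dropped and the anchor stays. Comparisons are strict, so a speed exactly
    at a threshold fails it. A zero elapsed time (infinite speed) drops the
    candidate with a warning.
    """
    if not track.fixes:
        return Track(track.session_id, [])
    if track.source != "argos":
        raise ValueError("speed_filter applies to Argos tracks")
    crs = crs or track_crs(track)
    xy = project_track(track, crs)
    times = track.times

    kept_idx = [0]
    for i in range(1, len(track.fixes)):
        a = kept_idx[-1]
        dt = times[i] - times[a]
        if dt <= 0:
            logger.warning(
                "track %s: fix at t=%s repeats the anchor timestamp; dropped",
                track.session_id, times[i],
            )
            continue
        d = float(np.hypot(*(xy[i] - xy[a])))
        v_kmh = d / dt * 3.6
        ok = v_kmh < cfg.cruise_speed or (
            v_kmh < cfg.max_speed and dt / 60.0 < cfg.max_accel_duration
        )
        if ok:
            kept_idx.append(i)
    return Track(track.session_id, [track.fixes[i] for i in kept_idx])


def retention_report(raw: Track, filtered: dict[str, Track]):
    """Per-class retained counts and percentages for each filter, as a DataFrame
    in the layout of a filter-performance table (classes as rows, filters as
    columns, a Total row last)."""
    import pandas as pd

    classes = ["3", "2", "1", "0", "A", "B"]
    raw_counts = {lc: sum(1 for f in raw.fixes if f.lc == lc) for lc in classes}
    rows = {}
    for lc in classes:
        row = {"Raw": raw_counts[lc]}
        for name, trk in filtered.items():
            row[name] = sum(1 for f in trk.fixes if f.lc == lc)
        rows[lc] = row
    total = {"Raw": sum(raw_counts.values())}
    for name, trk in filtered.items():
        total[name] = len(trk.fixes)
    rows["Total"] = total
    return pd.DataFrame.from_dict(rows, orient="index")
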