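"""Error-propagation experiments: how location error inflates home-range
estimates relative to error-free references.

Every experiment reduces to one comparison primitive: an error-affected
("Argos") point set is scored against a reference point set by estimating
both home ranges at matched sample size (the reference is repeatedly
subsampled to the Argos count), and reporting the Argos/reference area
ratio and the proportion of Argos points falling inside the reference
range. Scenarios differ only in how the two point sets arise: destructive
filtering of simulated sessions, error injection into GPS tracks, or
uniform points in disks of varying radius (the spatial-scale experiment).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geo import Track, project_track, track_crs
from .homerange import KDEConfig, HomeRange, kde95, mcp95, proportion_in_homerange
from .synthetic import ErrorSampler, uniform_disk

logger = logging.getLogger(__name__)

METHODS = ("mcp95", "kde95")


@dataclass(frozen=True)
class ScenarioSpec:
    """Configuration of one simulation scenario."""

    kind: str  # {filtered, static_injection, mobile_injection, circle}
    filter: str | None = None
    radius: float | None = None
    n_sessions: int = 20
    sim_reps: int = 100
    subsample_iters: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("filtered", "static_injection", "mobile_injection", "circle"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "circle" and (self.radius is None or self.radius <= 0):
            raise ValueError("circle scenario needs a positive radius")


@dataclass
class ComparisonMetrics:
    """Per-comparison outcome for one estimator.

    Areas in km²; ``ratio`` is Argos/reference area; ``prop_in_ref`` is the
    fraction of Argos points inside the reference home range. Spreads are
    SDs over the reference-subsampling iterations.
    """

    method: str
    n_points: int
    n_iters: int
    area_argos: float
    area_ref_mean: float
    area_ref_sd: float
    ratio_mean: float
    ratio_sd: float
    prop_in_ref_mean: float
    prop_in_ref_sd: float


def _estimate(method: str, pts: np.ndarray, kde_cfg: KDEConfig, level: float) -> HomeRange:
    if method == "mcp95":
        return mcp95(pts, level=level)
    if method == "kde95":
        cfg = kde_cfg if kde_cfg.level == level else KDEConfig(
            h=kde_cfg.h, cell=kde_cfg.cell, margin=kde_cfg.margin, level=level
        )
        return kde95(pts, cfg)
    raise ValueError(f"unknown method {method!r}")


def compare_to_reference(
    argos_pts,
    ref_pts,
    method: str | Sequence[str] = METHODS,
    iters: int = 1000,
    rng: np.random.Generator | None = None,
    kde_cfg: KDEConfig = KDEConfig(),
    level: float = 0.95,
) -> ComparisonMetrics | dict[str, ComparisonMetrics]:
    """Score an error-affected point set against an error-free reference.

    The Argos home range is estimated once per method. Each iteration draws,
    without replacement, as many reference points as there are Argos points,
    estimates the reference home range, and records the area ratio and the
    proportion of Argos points inside the reference range; means and SDs over
    iterations are returned. When the reference has exactly the Argos count
    the subsample is the full set, so a single iteration suffices and the
    spread is zero.

    *method* may be one method name (returns a single
    :class:`ComparisonMetrics`) or a sequence (returns a dict keyed by
    method); all methods share the same subsample draws.
    """
    argos = np.asarray(argos_pts, dtype=float)
    ref = np.asarray(ref_pts, dtype=float)
    n = len(argos)
    if n < 5:
        raise ValueError("need at least 5 Argos points")
    if len(ref) < n:
        raise ValueError(f"reference ({len(ref)}) smaller than Argos set ({n})")
    single = isinstance(method, str)
    methods = (method,) if single else tuple(method)

    degenerate = len(ref) == n
    eff_iters = 1 if degenerate else iters
    if not degenerate and rng is None:
        raise ValueError("rng required when the reference must be subsampled")

    hr_argos = {m: _estimate(m, argos, kde_cfg, level) for m in methods}
    ratios = {m: np.empty(eff_iters) for m in methods}
    areas = {m: np.empty(eff_iters) for m in methods}
    props = {m: np.empty(eff_iters) for m in methods}
    for it in range(eff_iters):
        sub = ref if degenerate else ref[rng.choice(len(ref), size=n, replace=False)]
        for m in methods:
            hr_ref = _estimate(m, sub, kde_cfg, level)
            areas[m][it] = hr_ref.area
            ratios[m][it] = hr_argos[m].area / hr_ref.area
            props[m][it] = proportion_in_homerange(argos, hr_ref)

    out = {}
    for m in methods:
        sd = lambda a: float(np.std(a, ddof=1)) if eff_iters > 1 else 0.0
        out[m] = ComparisonMetrics(
            method=m,
            n_points=n,
            n_iters=eff_iters,
            area_argos=hr_argos[m].area / 1e6,
            area_ref_mean=float(areas[m].mean()) / 1e6,
            area_ref_sd=sd(areas[m]) / 1e6,
            ratio_mean=float(ratios[m].mean()),
            ratio_sd=sd(ratios[m]),
            prop_in_ref_mean=float(props[m].mean()),
            prop_in_ref_sd=sd(props[m]),
        )
    return out[methods[0]] if single else out


def _metrics_rows(base: dict, metrics: Mapping[str, ComparisonMetrics]) -> list[dict]:
    rows = []
    for m, cm in metrics.items():
        rows.append(
            {
                **base,
                "method": m,
                "n_points": cm.n_points,
                "area_argos_km2": cm.area_argos,
                "area_ref_km2": cm.area_ref_mean,
                "ratio": cm.ratio_mean,
                "ratio_sd": cm.ratio_sd,
                "prop_in_ref": cm.prop_in_ref_mean,
                "prop_in_ref_sd": cm.prop_in_ref_sd,
            }
        )
    return rows


def run_circle_scenario(
    radii: Sequence[float],
    sampler: ErrorSampler,
    session_sizes: Sequence[int],
    rng: np.random.Generator,
    sim_reps: int = 100,
    subsample_iters: int = 1000,
    kde_cfg: KDEConfig = KDEConfig(),
) -> pd.DataFrame:
    """The spatial-scale experiment: uniform points in disks of varying radius.

    Per repeat and session, the reference is ``n`` points uniform in the
    disk; the Argos set is those same points perturbed by class-matched
    error draws (classes from the sampler's mix). Both estimators are scored
    per session; rows are per (radius, rep, session, method).
    """
    rows: list[dict] = []
    for radius in radii:
        for rep in range(sim_reps):
            for s, n in enumerate(session_sizes):
                ref = uniform_disk(int(n), float(radius), rng)
                lcs = sampler.draw_lc(rng, int(n))
                dx, dy = sampler.sample_classes(lcs, rng)
                argos = ref + np.column_stack([dx, dy])
                metrics = compare_to_reference(
                    argos, ref, METHODS, iters=subsample_iters, rng=rng, kde_cfg=kde_cfg
                )
                rows.extend(
                    _metrics_rows({"radius": radius, "rep": rep, "session": s}, metrics)
                )
    return pd.DataFrame(rows)


def run_injection_scenario(
    gps_tracks: Sequence[Track],
    sampler: ErrorSampler,
    lc_counts: Sequence[Mapping[str, int]],
    rng: np.random.Generator,
    sim_reps: int = 100,
    subsample_iters: int = 1000,
    kde_cfg: KDEConfig = KDEConfig(),
) -> pd.DataFrame:
    """Error injection into real (or simulated) GPS tracks.

    For each repeat and session, the configured number of positions per
    location class is drawn from the session's GPS track, perturbed with
    class-matched errors, and scored against the full GPS track. One
    ``lc_counts`` mapping (class -> count) is required per track, mirroring
    the field sessions' retained best-class fixes.
    """
    if len(lc_counts) != len(gps_tracks):
        raise ValueError("need one lc_counts mapping per GPS track")
    rows: list[dict] = []
    for rep in range(sim_reps):
        for s, (track, counts) in enumerate(zip(gps_tracks, lc_counts)):
            missing = [lc for lc in counts if lc not in sampler.params]
            if missing:
                raise KeyError(f"sampler lacks error model for classes {missing}")
            n = int(sum(counts.values()))
            crs = track_crs(track)
            ref = project_track(track, crs)
            idx = rng.choice(len(ref), size=n, replace=False)
            lcs = np.repeat(list(counts.keys()), list(counts.values()))
            rng.shuffle(lcs)
            dx, dy = sampler.sample_classes(lcs, rng)
            argos = ref[idx] + np.column_stack([dx, dy])
            metrics = compare_to_reference(
                argos, ref, METHODS, iters=subsample_iters, rng=rng, kde_cfg=kde_cfg
            )
            rows.extend(_metrics_rows({"rep": rep, "session": track.session_id}, metrics))
    return pd.DataFrame(rows)


def run_filter_scenario(
    argos_tracks: Sequence[Track],
    gps_tracks: Sequence[Track],
    filters: Mapping[str, Callable[[Track], Track] | None],
    rng: np.random.Generator,
    subsample_iters: int = 1000,
    kde_cfg: KDEConfig = KDEConfig(),
) -> pd.DataFrame:
    """Score filtered Argos sessions against their GPS tracks.

    *filters* maps a treatment name to a callable ``Track -> Track`` (or
    ``None`` for the raw data; an externally pre-filtered dataset can be
    passed by supplying its tracks and the identity). Sessions whose
    filtered set has fewer than 5 fixes are skipped with a logged warning.
    """
    if len(argos_tracks) != len(gps_tracks):
        raise ValueError("need paired Argos and GPS tracks")
    rows: list[dict] = []
    for argos_trk, gps_trk in zip(argos_tracks, gps_tracks):
        crs = track_crs(gps_trk)
        ref = project_track(gps_trk, crs)
        for name, fn in filters.items():
            filtered = argos_trk if fn is None else fn(argos_trk)
            if len(filtered) < 5:
                logger.warning(
                    "session %s, filter %s: only %d fixes left, skipped",
                    argos_trk.session_id, name, len(filtered),
                )
                continue
            argos = project_track(filtered, crs)
            metrics = compare_to_reference(
                argos, ref, METHODS, iters=subsample_iters, rng=rng, kde_cfg=kde_cfg
            )
            rows.extend(
                _metrics_rows({"filter": name, "session": argos_trk.session_id}, metrics)
            )
    return pd.DataFrame(rows)


def scale_experiment(
    seed: int,
    radii: Sequence[float] = (250.0, 500.0, 750.0, 1000.0, 2500.0, 5000.0),
    sim_reps: int = 10,
    subsample_iters: int = 100,
    n_sessions: int = 20,
    kde_cfg: KDEConfig = KDEConfig(),
) -> tuple[pd.DataFrame, np.ndarray]:
    """The headline spatial-scale study, end to end from one seed.

    Draws the per-session fix counts (normal 35 +/- 19, truncated at 5 — the
    best-two-classes session sizes of the field calibration), fits the
    mobile LC3/LC2 error model, and runs the disk experiment at the given
    radii. Returns the per-session rows and the session sizes used.
    """
    from .synthetic import mobile_lc32_sampler, session_sizes

    rng = np.random.default_rng(seed)
    sampler = mobile_lc32_sampler()
    sizes = session_sizes(n_sessions, rng)
    df = run_circle_scenario(
        list(radii), sampler, sizes, rng,
        sim_reps=sim_reps, subsample_iters=subsample_iters, kde_cfg=kde_cfg,
    )
    return df, sizes


def aggregate(df: pd.DataFrame, by: Sequence[str]) -> pd.DataFrame:
    """Average scenario rows over sessions/repeats, keeping *by* + method."""
    keys = list(by) + ["method"]
    agg = df.groupby(keys, as_index=False).agg(
        area_argos_km2=("area_argos_km2", "mean"),
        area_ref_km2=("area_ref_km2", "mean"),
        ratio=("ratio", "mean"),
        ratio_sd=("ratio", "std"),
        prop_in_ref=("prop_in_ref", "mean"),
        prop_in_ref_sd=("prop_in_ref", "std"),
    )
    agg["overestimation_pct"] = (agg["ratio"] - 1.0) * 100.0
    return agg
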