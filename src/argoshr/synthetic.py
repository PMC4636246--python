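"""Synthetic study data: GPS walking tracks, Argos fix schedules, and
per-location-class error samplers fitted to published calibration statistics.

The generator emulates the field protocol of a dual GPS/Argos accuracy
experiment: >4 h walking sessions recorded at 20 s intervals at ~3.4 km/h
(loops returning to camp, or one-way trips), Doppler fixes scattered along
the track with a realistic location-class mix, and location errors drawn
from right-skewed magnitude laws moment-matched to per-class published
means and SDs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import fieldstats
from .error_stats import LCErrorSummary, percentile
from .geo import CRS, Fix, Track, project_track, track_crs, unproject_xy

logger = logging.getLogger(__name__)

#: Default session start: 2012-07-01 12:00 UTC (epoch seconds).
DEFAULT_T0 = 1_341_144_000.0
#: Default camp position: open tundra at high latitude.
DEFAULT_ORIGIN = (-80.0, 73.0)


@dataclass(frozen=True)
class TrackSpec:
    """Parameters of a synthetic GPS walking session."""

    duration_h: float = 4.0
    fix_interval_s: float = 20.0
    mean_speed_kmh: float = 3.4
    speed_sd_kmh: float = 0.4
    shape: str = "loop"  # or "one_way"

    def __post_init__(self) -> None:
        if min(self.duration_h, self.fix_interval_s, self.mean_speed_kmh) <= 0:
            raise ValueError("duration, interval and mean speed must be positive")
        if self.shape not in ("loop", "one_way"):
            raise ValueError(f"unknown track shape {self.shape!r}")


def generate_gps_track(
    spec: TrackSpec,
    rng: np.random.Generator,
    session_id: str = "gps",
    origin: tuple[float, float] = DEFAULT_ORIGIN,
    t0: float = DEFAULT_T0,
) -> Track:
    """Simulate one GPS walking session.

    Per-step speeds are normal around the mean walking speed (floored at a
    slow shuffle). A loop session walks a smooth closed curve — a randomly
    deformed circle through camp, rescaled so its length equals the session's
    total path length — so the track ends where it started up to GPS jitter.
    A one-way session follows a correlated heading process away from the
    start. Every fix carries a few metres of positional jitter (receiver
    noise and gait wobble).
    """
    dt = spec.fix_interval_s
    n_steps = int(round(spec.duration_h * 3600.0 / dt))
    speeds = rng.normal(spec.mean_speed_kmh, spec.speed_sd_kmh, n_steps)
    speeds = np.maximum(speeds, 0.1 * spec.mean_speed_kmh)
    step_len = speeds / 3.6 * dt  # metres per step
    s = np.concatenate([[0.0], np.cumsum(step_len)])  # arclength at each fix

    if spec.shape == "loop":
        # closed base curve: circle deformed by low-order harmonics, anchored at camp
        phi0 = rng.uniform(0.0, 2 * np.pi)
        direction = rng.choice([-1.0, 1.0])
        amps = rng.uniform(0.04, 0.16, 3)
        phases = rng.uniform(0.0, 2 * np.pi, 3)
        u = np.linspace(0.0, 1.0, 4096)
        rho = 1.0 + sum(a * np.cos(2 * np.pi * k * u + p)
                        for k, a, p in zip((2, 3, 4), amps, phases))
        ang = direction * 2 * np.pi * u + phi0
        base = np.column_stack([rho * np.cos(ang), rho * np.sin(ang)])
        base -= base[0]  # start (and, by periodicity, end) at camp
        seg = np.hypot(*np.diff(base, axis=0).T)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        scale = s[-1] / arc[-1]  # curve length == total path length
        pos = np.column_stack([
            np.interp(s, arc * scale, base[:, 0] * scale),
            np.interp(s, arc * scale, base[:, 1] * scale),
        ])
    else:
        heading = rng.uniform(0, 2 * np.pi) + np.cumsum(rng.normal(0.0, 0.08, n_steps))
        steps = step_len[:, None] * np.column_stack([np.cos(heading), np.sin(heading)])
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])

    # GPS receiver noise: a few metres, strongly autocorrelated between
    # consecutive 20 s fixes, so it barely inflates the walked path length
    rho_ar, sd_ar = 0.95, 3.0
    innov = rng.normal(0.0, sd_ar * math.sqrt(1 - rho_ar**2), pos.shape)
    jitter = np.empty_like(pos)
    jitter[0] = rng.normal(0.0, sd_ar, 2)
    for i in range(1, len(pos)):
        jitter[i] = rho_ar * jitter[i - 1] + innov[i]
    pos = pos + jitter

    crs = CRS(*origin)
    lon, lat = unproject_xy(pos[:, 0], pos[:, 1], crs)
    fixes = [
        Fix(id=session_id, t=t0 + i * dt, lon=float(lon[i]), lat=float(lat[i]), source="gps")
        for i in range(n_steps + 1)
    ]
    return Track(session_id, fixes)


# ---------------------------------------------------------------------------
# error sampler

@dataclass(frozen=True)
class _LCParams:
    """Log-normal magnitude law (mu, sigma) and axis anisotropy scales."""

    mu: float | None  # None encodes a zero-error class
    sigma: float
    ax: float
    ay: float


@dataclass
class ErrorSampler:
    """Seedable per-location-class generator of planar (dx, dy) error vectors.

    Error magnitude follows a log-normal law; the direction is drawn
    uniformly and then stretched along the east axis by the anisotropy ratio
    ``ax:ay`` (Doppler errors are larger in longitude than latitude at high
    latitude), preserving the drawn magnitude.
    """

    params: dict[str, _LCParams]
    lc_mix: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lc_mix:
            tot = sum(self.lc_mix.values())
            if not math.isclose(tot, 1.0, abs_tol=1e-9):
                raise ValueError(f"lc_mix sums to {tot}, expected 1")

    @classmethod
    def zero(cls, lcs: Sequence[str], lc_mix: Mapping[str, float] | None = None) -> "ErrorSampler":
        """A sampler that returns (0, 0) for every class — the no-error limit."""
        return cls({lc: _LCParams(None, 0.0, 1.0, 1.0) for lc in lcs}, dict(lc_mix or {}))

    def classes(self) -> list[str]:
        return list(self.params)

    def scaled(self, factor: float) -> "ErrorSampler":
        """A copy with every error magnitude multiplied by *factor*."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        newp = {}
        for lc, p in self.params.items():
            if p.mu is None or factor == 0:
                newp[lc] = _LCParams(None, 0.0, p.ax, p.ay)
            else:
                newp[lc] = _LCParams(p.mu + math.log(factor), p.sigma, p.ax, p.ay)
        return ErrorSampler(newp, dict(self.lc_mix))

    def sample(self, lc: str, rng: np.random.Generator, size: int | None = None):
        """Draw one (or *size*) signed planar error vector(s) for class *lc*."""
        if lc not in self.params:
            raise KeyError(f"no error model for location class {lc!r}")
        p = self.params[lc]
        n = 1 if size is None else size
        if p.mu is None:
            dx = np.zeros(n)
            dy = np.zeros(n)
        else:
            mag = rng.lognormal(p.mu, p.sigma, n)
            phi = rng.uniform(0.0, 2 * np.pi, n)
            wx = p.ax * np.cos(phi)
            wy = p.ay * np.sin(phi)
            norm = np.hypot(wx, wy)
            dx = mag * wx / norm
            dy = mag * wy / norm
        if size is None:
            return float(dx[0]), float(dy[0])
        return dx, dy

    def sample_classes(self, lcs: Sequence[str], rng: np.random.Generator):
        """Draw one error vector per entry of *lcs* (vectorized per class)."""
        lcs = np.asarray(lcs)
        dx = np.zeros(len(lcs))
        dy = np.zeros(len(lcs))
        for lc in np.unique(lcs):
            mask = lcs == lc
            ddx, ddy = self.sample(str(lc), rng, size=int(mask.sum()))
            dx[mask] = ddx
            dy[mask] = ddy
        return dx, dy

    def draw_lc(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw location classes from the sampler's class mix."""
        if not self.lc_mix:
            raise ValueError("sampler has no location-class mix")
        classes = list(self.lc_mix)
        probs = np.array([self.lc_mix[c] for c in classes])
        return rng.choice(classes, size=size, p=probs / probs.sum())


def fit_error_sampler(
    summaries: Sequence[LCErrorSummary], lc_mix: Mapping[str, float] | None = None
) -> ErrorSampler:
    """Fit a per-class error sampler to published (mean, SD) error statistics.

    The magnitude law is log-normal with parameters solving the moment
    equations ``sigma² = ln(1 + (SD/mean)²)``, ``mu = ln(mean) - sigma²/2``;
    the axis anisotropy ratio comes from the published longitudinal and
    latitudinal mean errors. A summary with mean 0 yields a zero-error class;
    a non-positive SD with positive mean is rejected as infeasible.
    """
    params: dict[str, _LCParams] = {}
    for s in summaries:
        if s.lc == "Total":
            continue
        if s.mean == 0:
            params[s.lc] = _LCParams(None, 0.0, 1.0, 1.0)
            continue
        if s.sd <= 0:
            raise ValueError(f"class {s.lc}: SD must be positive to fit a magnitude law")
        cv2 = (s.sd / s.mean) ** 2
        sigma2 = math.log1p(cv2)
        mu = math.log(s.mean) - sigma2 / 2.0
        ax, ay = (s.mean_x, s.mean_y) if (s.mean_x > 0 and s.mean_y > 0) else (1.0, 1.0)
        params[s.lc] = _LCParams(mu, math.sqrt(sigma2), ax, ay)
    mix = dict(lc_mix) if lc_mix is not None else None
    if mix is None:
        tot = sum(s.n for s in summaries if s.lc != "Total")
        mix = {s.lc: s.n / tot for s in summaries if s.lc != "Total"}
    return ErrorSampler(params, mix)


def mobile_lc32_sampler() -> ErrorSampler:
    """The default error model for the simulations: log-normal fits to the
    mobile-transmitter LC3 and LC2 calibration rows, mixed by their field
    frequencies."""
    return fit_error_sampler(
        [fieldstats.MOBILE["3"], fieldstats.MOBILE["2"]], lc_mix=fieldstats.LC32_MIX
    )


def static_lc32_sampler() -> ErrorSampler:
    """Same mix, but error magnitudes fitted to the static-transmitter rows."""
    return fit_error_sampler(
        [fieldstats.STATIC["3"], fieldstats.STATIC["2"]], lc_mix=fieldstats.LC32_MIX
    )


def sampler_fit_report(
    sampler: ErrorSampler,
    targets: Sequence[LCErrorSummary],
    rng: np.random.Generator,
    n: int = 100_000,
) -> pd.DataFrame:
    """Compare empirical statistics of sampler draws against their fit targets.

    Used as a fit-quality log: moment-matched means/SDs should agree closely,
    while medians and percentiles show how well the log-normal shape stands
    in for the (unavailable) empirical error distribution.
    """
    rows = []
    for s in targets:
        if s.lc == "Total" or s.lc not in sampler.params:
            continue
        dx, dy = sampler.sample(s.lc, rng, size=n)
        mag = np.hypot(dx, dy)
        rows.append(
            {
                "lc": s.lc,
                "mean_target": s.mean, "mean_fit": mag.mean(),
                "sd_target": s.sd, "sd_fit": mag.std(ddof=1),
                "median_target": s.median, "median_fit": percentile(mag, 0.5),
                "p68_target": s.p68, "p68_fit": percentile(mag, 0.68),
                "p90_target": s.p90, "p90_fit": percentile(mag, 0.90),
            }
        )
    report = pd.DataFrame(rows)
    for _, r in report.iterrows():
        logger.info(
            "LC%s fit: mean %.0f/%.0f sd %.0f/%.0f p68 %.0f/%.0f p90 %.0f/%.0f (fit/target)",
            r["lc"], r["mean_fit"], r["mean_target"], r["sd_fit"], r["sd_target"],
            r["p68_fit"], r["p68_target"], r["p90_fit"], r["p90_target"],
        )
    return report


def save_sampler(sampler: ErrorSampler, path) -> None:
    """Persist sampler parameters as a YAML config, so a simulation can be
    re-run from its recorded error model."""
    import yaml

    doc = {
        "lc_mix": {k: float(v) for k, v in sampler.lc_mix.items()},
        "classes": {
            lc: None if p.mu is None else {
                "mu": float(p.mu), "sigma": float(p.sigma),
                "ax": float(p.ax), "ay": float(p.ay),
            }
            for lc, p in sampler.params.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_sampler(path) -> ErrorSampler:
    """Inverse of :func:`save_sampler`."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    params = {
        lc: _LCParams(None, 0.0, 1.0, 1.0) if spec is None
        else _LCParams(spec["mu"], spec["sigma"], spec["ax"], spec["ay"])
        for lc, spec in doc["classes"].items()
    }
    return ErrorSampler(params, dict(doc.get("lc_mix") or {}))


# ---------------------------------------------------------------------------
# spatial draws and Argos sessions

def uniform_disk(n: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """n points i.i.d. uniform over a disk of the given radius, centered at the
    origin: r = R sqrt(u) with a uniform angle."""
    if n < 1 or radius <= 0:
        raise ValueError("need n >= 1 and radius > 0")
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2 * np.pi, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def generate_argos_session(
    track: Track,
    sampler: ErrorSampler,
    rng: np.random.Generator,
    n_mean: float = fieldstats.SESSION_SIZE[0],
    n_sd: float = fieldstats.SESSION_SIZE[1],
    lc_mix: Mapping[str, float] | None = None,
    session_id: str | None = None,
) -> Track:
    """Simulate the Argos fixes of one session over a GPS track.

    Session size is normal(n_mean, n_sd) rounded and truncated at 5 (so
    home-range estimation stays well-posed); fix times are a random
    subsequence of the GPS timestamps; classes follow *lc_mix* (default: the
    sampler's mix); positions are the GPS truth perturbed by class-matched
    error draws.
    """
    if not track.fixes:
        raise ValueError("empty GPS track")
    n = max(5, int(round(rng.normal(n_mean, n_sd))))
    n = min(n, len(track.fixes))
    idx = np.sort(rng.choice(len(track.fixes), size=n, replace=False))
    mix = dict(lc_mix) if lc_mix is not None else sampler.lc_mix
    classes = list(mix)
    probs = np.array([mix[c] for c in classes])
    lcs = rng.choice(classes, size=n, p=probs / probs.sum())

    crs = track_crs(track)
    xy = project_track(track, crs)[idx]
    dx, dy = sampler.sample_classes(lcs, rng)
    lon, lat = unproject_xy(xy[:, 0] + dx, xy[:, 1] + dy, crs)

    sid = session_id or f"{track.session_id}-argos"
    fixes = [
        Fix(id=sid, t=float(track.fixes[i].t), lon=float(lon[k]), lat=float(lat[k]),
            lc=str(lcs[k]), source="argos")
        for k, i in enumerate(idx)
    ]
    return Track(sid, fixes)


def session_sizes(
    n_sessions: int,
    rng: np.random.Generator,
    mean: float = fieldstats.LC32_SESSION_SIZE[0],
    sd: float = fieldstats.LC32_SESSION_SIZE[1],
    minimum: int = 5,
) -> np.ndarray:
    """Per-session fix counts: normal(mean, sd), rounded, truncated below."""
    raw = np.round(rng.normal(mean, sd, n_sessions)).astype(int)
    return np.maximum(raw, minimum)
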