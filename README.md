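# argoshr — Argos location error and its effect on home-range estimates

Argos satellite telemetry locates an animal-borne transmitter (PTT) from the
Doppler shift of its messages and labels each fix with a location class
(LC3, 2, 1, 0, A, B; Z = invalid) rather than an exact error. For wildlife
studies this error — hundreds of metres for the best classes, kilometres for
the worst — propagates directly into downstream quantities such as
home-range size. This package implements, for movement ecologists, the full
evaluation pipeline for that problem in a high-latitude terrestrial setting:

- **Error measurement** against GPS truth: static references (mean of GPS
  fixes at a site) and mobile references (linear interpolation of a walking
  GPS track at each Argos timestamp, only across GPS gaps < 10 min), with
  per-class summary tables (mean ± SD, absolute longitudinal/latitudinal
  components, median, 68th and 90th percentiles).
- **Destructive filtering**: best-class retention (LC3 / LC32 / LC321) and a
  speed filter that keeps a fix only if the speed from the last retained fix
  is below a cruise speed (6 km/h), or below a burst speed (8 km/h)
  sustained for less than 20 min.
- **Home-range estimators**: the 95% minimum convex polygon (convex hull of
  points within the 95% quantile of centroid distance) and the 95% fixed
  kernel (bivariate-normal utilization distribution on a 250 m grid with
  h = 850 m; the home range is the smallest cell set holding 95% of the
  mass), plus the reference bandwidth h = sqrt((var x + var y)/2) · n^(-1/6).
- **Error-propagation simulations**: filtered, error-injected and
  uniform-disk scenarios, each scored by the Argos/reference area ratio and
  the proportion of Argos points inside the reference range, at matched
  sample size via reference subsampling.
- **A synthetic field campaign**: seedable generators for GPS walking
  sessions (>4 h loops at 3.4 ± 0.4 km/h, fixes every 20 s), Argos fix
  schedules (64 ± 20 fixes per session with a realistic class mix), and
  per-class error vectors from log-normal magnitude laws moment-matched to
  published tundra calibration statistics. No field data are required to run
  anything here.

## Worked example

```python
import numpy as np
from argoshr import (TrackSpec, generate_gps_track, generate_argos_session,
                     mobile_lc32_sampler, compare_to_reference,
                     track_crs, project_track)

rng = np.random.default_rng(1)
gps = generate_gps_track(TrackSpec(shape="loop"), rng, session_id="S01")
argos = generate_argos_session(gps, mobile_lc32_sampler(), rng)

crs = track_crs(gps)
m = compare_to_reference(project_track(argos, crs), project_track(gps, crs),
                         method="mcp95", iters=100, rng=rng)
print(f"MCP area {m.area_argos:.1f} km2 vs reference {m.area_ref_mean:.1f} km2;"
      f" ratio {m.ratio_mean:.2f}")
```

prints

```
MCP area 21.9 km2 vs reference 13.3 km2; ratio 1.65
```

i.e. on this simulated 4-hour session the location error of the raw Argos
fixes inflates the 95% MCP home range to about 1.7 times the size estimated
from the same number of true GPS positions.

The `analysis/` directory walks the whole study as numbered scripts:
`01_calibrate_error_model.py` (fit quality of the error law),
`02_simulate_field_sessions.py` (the synthetic campaign),
`03_error_summary.py` (per-class error table), `04_filter_comparison.py`
(class filters vs the speed filter), `05_injection_experiment.py`
(static vs mobile error injection) and `06_scale_experiment.py` (disk
radii 250 m – 5 km). Each writes tidy tables under `results/`. A thin CLI
(`argoshr synth|filter|error-summary|homerange|simulate`) exposes the same
operations on fix tables.

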