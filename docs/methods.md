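# Methods

This note documents the models, conventions and numerical choices behind
`argoshr`, and what the synthetic data do and do not establish.

## Planar frame and error measurement

All geometry is computed in a local azimuthal-equidistant projection on a
spherical earth (R = 6 371 000 m), centered per session on the track
centroid. At the study's spatial extent (≤ ~10 km) the distortion of this
frame is below a millimetre over 50 km round trips — orders of magnitude
under Doppler location error — and it avoids UTM zone edges near 80°W/73°N.
No published projection choice exists for this kind of analysis; absolute
error magnitudes could differ from an ellipsoidal implementation by well
under 0.5%.

A static site's reference position is the arithmetic mean of all its GPS
fixes. A mobile Argos fix gets its reference by linear interpolation of the
bracketing GPS fixes at the Argos timestamp, but only when the bracketing
gap is strictly shorter than 10 minutes: a Doppler timestamp is the midpoint
of a satellite pass (~10 min), so interpolating across wider GPS outages
would not represent the transmitter's true position. Fixes outside the GPS
time span are dropped (no extrapolation), with a logged count. The error
record keeps the signed east/north components and their Euclidean norm.

Timestamps are UTC seconds since the epoch; table input requires an
explicit zone marker or assumes UTC with a warning.

## Error summaries

Per location class we report n, the proportion of fixes, mean ± SD of the
total error, the mean ± SD of the *absolute* east and north components,
the median, and the 68th/90th percentiles (the 68th is the Argos system's
advertised accuracy statistic). Signed axis means would be near zero by
symmetry, so the absolute-value reading is the one consistent with
published accuracy tables; this is an interpretation, recorded here.
Quantiles use linear interpolation between order statistics at rank
1 + p(n−1) (the ubiquitous "type 7" rule); at the sample sizes involved the
choice of rule is immaterial. Invalid (LCZ) fixes are excluded with a
logged count.

## Destructive filters

Class filters keep a fix set {LC3}, {LC3,2} or {LC3,2,1}. The speed filter
scans the track once, comparing each candidate to the last *retained* fix:
with planar speed v and elapsed time Δt, the candidate is kept iff
v < cruise_speed (default 6 km/h), or v < max_speed (8 km/h) with
Δt < max_accel_duration (20 min). Comparisons are strict; the first fix is
retained unconditionally (it has no predecessor to be judged against). The
retained-fix anchor matters after consecutive drops and is pinned by an
exhaustive brute-force oracle in the test suite. The Douglas Argos filter
is an external published tool; its output can be ingested as a pre-filtered
fix table but it is not reimplemented here.

## Home-range estimators

**MCP.** The 95% minimum convex polygon retains the points whose distance
to the arithmetic centroid is at most the type-7 95% quantile of those
distances, then takes the convex hull. This is the behaviour of the
standard home-range software (adehabitat's `mcp`) rather than a
keep-ceil(0.95 n) rule; for n = 35 it retains 33 points instead of 34. The
difference is one extreme point, which matters a great deal when hulls are
error-dominated — the quantile rule is the one that reproduces
field-calibrated inflation figures.

**Kernel.** The utilization distribution is a bivariate-normal kernel
density with fixed bandwidth h = 850 m, evaluated at the centers of a 250 m
grid covering the point bounding box expanded by a 4h margin (beyond which
kernel mass is negligible). The grid origin snaps to multiples of the cell
size so equal point sets on the same frame share cell boundaries. Cell
masses are renormalized to sum to one, making the isopleth well-defined on
the finite grid; the 95% home range is the smallest prefix of cells, ranked
by mass (row-major index breaking ties, for determinism), reaching 95% of
the mass, and its area is the cell count × cell². h = 850 m is the study
configuration constant (the mean ad hoc bandwidth over its filtering
treatments); the ad hoc formula h = sqrt((var x + var y)/2)·n^(−1/6) is
provided but not used to re-derive it. Containment in a kernel range means
falling inside an occupied isopleth cell.

## Synthetic field campaign

The generator emulates the calibration protocol, not any particular
dataset:

- **GPS sessions**: 4 h at 20 s intervals (721 fixes), per-step speeds
  normal(3.4, 0.4) km/h floored at a slow shuffle. A loop session walks a
  smooth closed curve — a circle deformed by 2nd–4th harmonic radial
  perturbations (amplitudes 0.04–0.16), anchored at camp and rescaled so
  the curve length equals the session's drawn path length — so tracks close
  within tens of metres by construction. One-way sessions follow a
  correlated heading walk. Receiver noise is AR(1) (sd 3 m, lag
  correlation 0.95 per fix), matching the strong short-lag autocorrelation
  of GPS error and leaving the realized walking speed essentially unbiased.
- **Argos sessions**: size normal(64, 20) rounded and truncated at 5 (so
  home-range estimation stays well-posed), fix times a random subsequence
  of GPS timestamps, classes multinomial with the published mobile mix
  (20.94 / 34.35 / 25.65 / 12.63 / 2.12 / 4.31% for LC3…B).
- **Error model**: per class, the error magnitude is log-normal with
  parameters solving the published (mean, SD) moment equations
  (σ² = ln(1 + (SD/mean)²), μ = ln mean − σ²/2); the direction is uniform,
  stretched along the east axis by the ratio of the published longitudinal
  to latitudinal mean errors (Doppler errors are larger in longitude at
  high latitude), preserving the drawn magnitude. Axis components are
  therefore dependent in magnitude but independent in sign; whether the
  original axis draws were joint or independent is unknowable without the
  raw data, and the log-normal is an explicit stand-in for the empirical
  magnitude law. Fit quality is logged, not asserted: means/SDs match by
  construction (<1% at 10⁵ draws) and p90 agrees within ~5%, but the
  fitted mobile-LC3 p68 is ~6% under the published 643 m — the log-normal
  mid-body is slightly lighter than the empirical distribution.

What passing tests on these data do **not** show: the generator has no
pass-to-pass error correlation (real consecutive Argos fixes from one
satellite pass share error), no message-count or pass-geometry structure,
and its loop tracks are smoother than real terrain-constrained walking. The
independence of consecutive errors makes the speed filter noticeably
harsher on synthetic sessions than it was in the field (it removes ~70% of
synthetic fixes vs ~38% reported on real data), so filter *retention rates*
here are generator artefacts; the home-range orderings across filters are
the meaningful output.

## Comparison primitive and scenarios

Every experiment scores an error-affected point set against an error-free
reference at matched sample size: the Argos home range is estimated once,
and each iteration draws (without replacement — with replacement would
duplicate points and degenerate hulls) as many reference points as there
are Argos points, estimates the reference range, and records the area ratio
and the proportion of Argos points inside the reference range. Metrics are
averaged per session over iterations, then over sessions and repeats,
keeping sessions equally weighted; the per-iteration-ratio mean (not the
ratio of mean areas) is the reported statistic. In the disk scenario the
reference set has exactly the Argos count, so the subsample is the identity
permutation and a single iteration suffices (zero spread); the code
short-circuits accordingly.

Scenario defaults follow the study design: 20 sessions; disk radii 250,
500, 750, 1000, 2500, 5000 m; session sizes normal(35, 19) truncated at 5
(the best-two-classes per-session counts); LC3:LC2 mixed 267:438. The full
design used 100 repeats × 1000 subsample iterations; the packaged runs use
10 × 100, which leaves the aggregate overestimation percentages stable to
within a few percent across seeds while keeping every script and the test
suite in the seconds-to-minutes range. Both are configurable.

At local scales the two estimators fail differently, and the simulations
reproduce this mechanism: the MCP hull is driven by the largest error draws
(overestimation of thousands of percent at r = 250 m, diluting as the true
extent grows), whereas the kernel area is bandwidth-dominated for extents
≪ h — a single point already yields π(h·sqrt(−2 ln 0.05))² ≈ 13.6 km² at
h = 850 m — so error inflates it modestly (~50–60%) and containment of
perturbed points stays near-total below 1 km radii.

## Determinism

All randomness flows through one `numpy.random.Generator` seeded at the
entry point; scenario runs, generators and the acceptance script replay
byte-identically under a fixed seed, and run manifests record seed and
configuration.

## Known limitations

- The log-normal magnitude law reproduces moments and the upper decile of
  the calibration rows, not their exact shape; tail-sensitive quantities
  (the 250 m MCP inflation above all) carry the approximation.
- MCP containment of points sampled along a closed loop track is
  chord-limited (points on a convex-ish curve lie outside the hull of a
  subsample), so proportion-in-reference for MCP on loop geometries is
  structurally low; the kernel metric does not share this artefact.
- No state-space or error-aware movement modelling: filters here are
  destructive by design.
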