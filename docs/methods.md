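# Methods

This note documents the models, conventions and numerical choices behind
`settrack`, in the order data flow through the pipeline.

## Scope and frames

All computation happens in a projected metric frame, by default UTM zone
29N (EPSG:32629), which contains the simulated study area in County Down.
The projection is the Krüger n-series transverse Mercator (6th order in
the third flattening; sub-millimetre error within a zone) and geodesic
distances use Vincenty's inverse formula on WGS84; both live in
`settrack.geo` and are exercised against independent oracles in the test
suite (spherical haversine for distances, round-trip closure for the
projection).

Body frame: **x forward, y left, z up**.  Heading is degrees clockwise
from north in [0, 360).  Pitch is positive nose-up, roll positive when the
left side rises.  The de-tilted compass reads `heading = atan2(-m_y, m_x)`
of the levelled magnetic field; the synthetic magnetometer is rendered
with the same convention, and the explicit rotation-matrix oracle in
`tests/test_sensors.py` pins it down.  Declination is taken as zero
(magnetic = geographic north) and the Earth field as a fixed vector with
configurable inclination (default 68°, appropriate for Ireland): a
dead-reckoning study over a few km² gains nothing from an IGRF lookup.

## Synthetic study (module `simulate`)

The generator stands in for an unavailable field data set, so its defaults
*are* the study conditions and are not tuned per experiment:

- two animals, seven nights each; sensors 40 Hz (acceleration,
  magnetometry) and 7 Hz (temperature, carried sample-and-hold on the
  40 Hz grid with validity flags);
- GPS every 3600 s between 21:00 and 04:00 with isotropic Gaussian error,
  σ = 10 m per axis.  The collars' real fix error is unpublished; 10 m is
  a typical open-field figure and is configurable.  Fixes scheduled while
  the animal is below ground are withheld (no sky view) and the schedule
  records the gap;
- movement is a correlated random walk: per-sample heading increments
  N(0, 0.7°) at 40 Hz (decorrelation time ≈ 5 min, which yields
  hourly net displacements of a few hundred metres — enough signal to
  calibrate against hourly GPS), over per-second behavioural states
  (stationary / forage ≈ 0.22 m/s / travel ≈ 0.45 m/s) with mean dwells of
  45/40/30 s and a per-night activity multiplier.  Nights begin and end at
  the animal's sett: emergence shortly before 21:00, a homing dash toward
  the sett around 03:20, and an optional mid-night below-ground bout
  (15–40 min, probability 0.5).  Nightly true path lengths land in the
  2.5–5.5 km range, matching the few-km regime reported for farmland
  badgers;
- the track is confined to the landscape bounding box by reflective
  folding.  Stored speed and heading are the *realised* per-step values,
  so "positions are the cumulative integral of speed·dt along heading"
  holds to machine precision even across a reflection;
- sensors are rendered from the truth: VeDBA target
  `max(0, (speed − c)/m) + noise` with m = 2.0 m s⁻¹ g⁻¹, c = 0 (so the
  travelling level is ≈ 0.22 g, the field-typical quarter-g), a dampened
  0.04 g floor below ground and a 0.01 g resting level above; the dynamic
  acceleration is 2–8 Hz band-limited noise scaled per sample to that
  magnitude (only the magnitude matters downstream), added to gravity
  rotated by slow (±15°, 0.15 Hz low-passed) pitch/roll; collar
  temperature relaxes first-order (τ = 450 s) toward ambient +4 °C below
  ground, so the rise over 30 min is ≈ the full offset;
- the landscape is a rectangular field grid separated by 5 m hedge strips
  plus a building and a road in the margin — enough structure for
  proximity analysis, not an attempt at real cartography.

Everything derives from one root seed (per-animal/night/stage
sub-streams), and equal configurations reproduce outputs bit for bit.

What the generator does *not* emulate: GPS fix failure above ground,
multipath error correlation, magnetometer hard/soft-iron distortion
(a calibration hook accepts a user matrix for real data), terrain,
social behaviour, or habitat-selective movement.  Passing tests therefore
demonstrate the *mechanics* of the pipeline — recovery of known
parameters under realistic noise — not ecological realism of any
particular number.

## Sensor processing (module `sensors`)

Static acceleration is a centred 2-s running mean per axis (81 samples at
40 Hz; the common biologging convention), shrinking at the record edges;
when the window equals the record the global mean is used.  VeDBA is the
L2 norm of raw − static.

Sett occupancy: the field observation is that VeDBA dampens *immediately
and persistently* below ground, whereas an active animal above ground
keeps spiking above the threshold even between pauses.  Mean VeDBA is a
poor discriminant — a night of a few km at m = 2 m s⁻¹ g⁻¹ implies a mean
above-ground VeDBA well below 0.1 g — so the detector is run-length
based: a below-ground bout is a *continuous* run of 5-s-smoothed VeDBA
below 0.1 g lasting at least 5 min; shorter dips (pauses) never qualify,
and short above-threshold gaps between qualifying bouts are closed.  A
≥ 3 °C temperature rise within 30 min of entry upgrades the evidence tag
to "both"; timing always comes from the VeDBA edge because the
thermometer lags.  On the synthetic nights this yields ≈ 99% sample-wise
agreement with truth; residual error is transition blur (± half the
smoothing window) plus the occasional > 5-min above-ground pause.

## Dead-reckoning (module `reckon`)

Speed model: `v = m·VeDBA + c`, clamped at zero, with intercept fixed at
0 by default (the calibration adjusts a gradient only) and a **movement
threshold** of 0.05 g below which v = 0.  The threshold matters: resting
dynamic acceleration during pauses otherwise integrates into phantom
displacement aligned with the persistent heading, which both inflates
path length and attenuates the calibrated gradient (errors-in-variables
dilution — measured at ≈ 7% low bias on the synthetic nights without it).

Calibration is per night and global (a single gradient), matching the
idea of altering one speed~VeDBA gradient until GPS and dead-reckoned
positions accord: segment displacement vectors per unit gradient are
regressed on the GPS displacement vectors; with c = 0 the least-squares
update converges in one step, and iteration (tolerance 1e-4, cap 50) is
kept for the general case.  Fixes below ground are discarded first.

Correction distributes the residual at each fix linearly in time across
its segment (current-style correction), holds the nearest residual
constant before the first and after the last fix, and therefore passes
through every usable fix exactly while preserving the dead-reckoned turn
structure within segments.  Nights with no usable fix return the
uncorrected track tagged `dead_reckoned_unanchored`; fully below-ground
records return an empty track.  On default synthetics the corrected track
is ~10–20 m RMS from truth, versus ~90–160 m for straight-line
interpolation between the hourly fixes.

## Space use (module `spaceuse`)

Path length: summed Vincenty geodesics between consecutive coordinates.
Outlier trimming removes the ⌈5%·n⌉ locations farthest (Euclidean,
projected) from the centroid — the canonical MCP95 convention; KD95 uses
the *same* trimmed set so GPS/dead-reckoned comparisons are like for
like.  MCP is the shapely convex hull (degenerate inputs flagged, zero
area).  KD95 is a binned Gaussian KDE: 2-D histogram on a 200×200 grid
covering the extent plus 3 bandwidths, Gaussian-filtered, normalised;
the range is the smallest set of highest-density cells reaching 95% mass,
polygonised as the exact union of those cells (so reported area equals
polygon area identically).  Default bandwidth is the ad-hoc reference
rule h = σ̂·n^(−1/6) (σ̂ = mean marginal SD), recorded in the output
metadata; fixed bandwidths are accepted.  Grid discretisation error is
< 2% (doubling test) and the analytic χ²₂ region of an isotropic normal
is matched within a few percent.

Proximity: per class, polygons are buffered by 20 m and dissolved before
the point-in-polygon test (no double counting within a class); classes
stay non-exclusive across classes, so proportions need not sum to 1.
Time weighting: count/40 Hz for dead-reckoned samples, 1 h per hourly GPS
fix.  A missing fix contributes no time anywhere — a documented
limitation of the fix-counting convention.

## Statistics (module `stats`)

All tests two-sided.  GPS vs dead-reckoned metrics: classical paired t
over badger-nights pooled across animals (df = n−1).  Between animals:
Welch t with Satterthwaite df.  Land use: one-way linear model
(value ~ feature class) with all six Tukey HSD contrasts; building/road
proportions are log10(x+1)-transformed because many nights are zero.  No
multiple-testing correction is applied across the four per-class paired
tests — a deliberate caveat, kept for comparability with standard
practice in this literature.  Degenerate inputs are reported, not raised:
zero-variance non-zero paired differences give ±∞ with a flag; an
all-identical land-use table gives F = 0, p = 1 (guarded with a tolerance
absorbing grand-mean float residue).

## Problem sizes and determinism

The shipped analyses use the full study scale: 2 animals × 7 nights ×
8 h × 40 Hz ≈ 16 M sensor samples, processed vectorised; the end-to-end
study plus a 20-replicate parameter-recovery run completes in a few
minutes on one CPU.  Unit tests use a reduced configuration (one 2-h
night at 20 Hz) through the identical code paths.  All stochastic stages
draw from generators seeded deterministically from the root seed, and the
manifest hashes written by `run_simulate` make byte-level reproducibility
checkable.

## Known limitations

- The speed~VeDBA relation is linear with zero intercept; real gait
  changes (trot/gallop, substrate) bend it.  Per-segment gradient
  overrides exist in `SpeedModel` but are not fitted by default.
- Heading assumes a rigid, well-aligned collar; collar roll on a real
  neck adds bias that only a field calibration can remove.
- The GPS error model is white and isotropic; real fix errors are
  autocorrelated and habitat-dependent.
- KD95 areas depend on the bandwidth rule; the reference rule is
  reported alongside the area so comparisons can be re-run under
  href-style or fixed bandwidths.
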