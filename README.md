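# settrack

GPS-enabled dead-reckoning of European badger (*Meles meles*) movement.

Hourly GPS fixes describe a badger's night as a handful of straight lines.
The collar's motion sensors record far more: tri-axial acceleration and
magnetometry at 40 Hz, temperature at 7 Hz.  `settrack` turns those streams
into the fine-scale track between the fixes and quantifies how the picture
of space use changes when you do — longer, more tortuous paths, sharper
core areas, more time attributed to linear features such as hedgerows.
Because raw collar data of this kind are rarely deposited, the package
ships a first-class synthetic-data module that simulates the whole study —
animals, sensors, GPS and landscape — with known ground truth, so every
stage is testable end to end.

It is written for movement ecologists and biologging methodologists who
want a transparent, scriptable alternative to GUI dead-reckoning tools.

## The method

1. **Sett occupancy.** VeDBA (vectorial dynamic body acceleration,
   `‖a_dynamic‖₂` after removing a 2-s running-mean gravity estimate)
   dampens immediately when the animal goes below ground (from an active
   level of ~0.25 g to < 0.1 g) while collar temperature rises by ~4 °C
   within half an hour.  Below-ground bouts are continuous sub-threshold
   VeDBA runs ≥ 5 min, corroborated by the temperature rise.
2. **Dead-reckoning.** Speed is taken proportional to VeDBA,
   `v = m·VeDBA + c` (clamped at 0, with a 0.05 g movement threshold), and
   integrated along the tilt-compensated compass heading at 40 Hz:
   `Δe = v·dt·sin(h)`, `Δn = v·dt·cos(h)`.
3. **GPS anchoring.** The gradient `m` is rescaled so dead-reckoned
   displacement between consecutive fixes matches the GPS displacement
   (least squares over segments), and the residual at each fix is
   distributed linearly over the samples of the segment, so the corrected
   track passes through every fix.
4. **Space use.** Per-night geodesic path lengths (WGS84); MCP95 and KD95
   home ranges after trimming the outermost 5% of locations; time within
   20 m of fields, hedges, buildings and roads (1 h per GPS fix, 1/40 s
   per dead-reckoned sample) — all in UTM zone 29N.
5. **Statistics.** Paired t-tests (GPS vs dead-reckoned, over
   badger-nights), Welch t-tests (between animals), and a one-way linear
   model with Tukey HSD contrasts across habitat classes
   (log10(x+1)-transformed for buildings/roads).

## Worked example

```python
from settrack.pipeline import SimConfig, simulate_bundle, analyse_bundle

bundle = simulate_bundle(SimConfig(seed=11))   # 2 badgers x 7 nights
result = analyse_bundle(bundle)
print(result.summary)
```

prints (abridged):

```
nightly path length (km): dead_reckoned: 4.25 +/- 0.52; gps: 1.19 +/- 0.22
dead-reckoned / GPS mean path ratio: 3.58
proportion of night within 20 m of hedge: dead_reckoned: 0.243; gps: 0.187
home range animal 0 MCP95 (gps): 0.503 km^2
home range animal 0 KD95 (gps): 0.970 km^2
home range animal 0 MCP95 (dead_reckoned): 0.724 km^2
home range animal 0 KD95 (dead_reckoned): 0.488 km^2
accuracy vs truth: dead-reckoned RMS 13.0 m; straight-line GPS interpolation RMS 114.5 m
```

Read it as: the dead-reckoned track is several times longer than the GPS
polyline (tortuosity the hourly fixes cannot see), its convex-hull range is
*larger* (excursions between fixes) while its kernel range is *smaller*
(dense points concentrate the utilisation distribution into real core
areas), it shifts time from open fields toward hedgerows, and against the
simulation's ground truth it is roughly an order of magnitude more accurate
than interpolating between fixes.

The same pipeline runs from the shell:

```sh
settrack simulate --seed 11 --out study/
settrack analyse  --out study/          # writes CSV/GeoJSON + summary.txt
```

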