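# hotcube

Spatiotemporal hotspot analysis of urban point events — built for injury
epidemiologists and transport-safety analysts who need to know not only
*where* incidents such as elderly-involved traffic accidents cluster, but
*when* those clusters are active and how they are trending.

The package chains five standard spatial-statistics stages over a table of
geocoded, timestamped events:

1. **Planar KDE** with the geographic plug-in bandwidth
   `radius = 0.9 · min(SD, √(1/ln 2) · D_m) · n^(−1/5)`, where `SD` is the
   standard distance about the mean centre and `D_m` the median distance to
   it; quartic kernel by default.
2. **Getis-Ord Gi\*** on square-cell counts with binary distance-band
   weights `w_ij`:

   ```
   z_i = [ Σ_j w_ij x_j − X̄ Σ_j w_ij ]
         / ( S · √( [n Σ_j w_ij² − (Σ_j w_ij)²] / (n−1) ) )
   ```

   with the usual 90/95/99 % confidence classes (|z| ≥ 1.65, 1.96, 2.58),
   plus an incremental-autocorrelation scan (global Moran's I z over a
   ladder of band distances) to choose the analysis scale.
3. **Space-time cubes** — count tensors over (row, col, t) with either a
   cyclic 24-hour axis (diurnal patterns) or calendar months (seasonal
   patterns) — and per-slice Gi\* fields.
4. **Emerging-hotspot analysis**: space-time Gi\* (spatial neighbours
   across a trailing time window) plus a per-cell Mann-Kendall trend test,
   classifying every cell into one of 17 categories (new, consecutive,
   intensifying, persistent, diminishing, sporadic, oscillating,
   historical — hot and cold — or no pattern).
5. **STKDE** — space-time kernel density with product Epanechnikov kernels

   ```
   f(x,y,t) = 1/(n h_s² h_t) Σ_i Ks((x−x_i)/h_s, (y−y_i)/h_s) · Kt((t−t_i)/h_t)
   Ks(u,v) = (2/π)(1 − u² − v²)  on u²+v² < 1      Kt(w) = ¾(1 − w²)  on w² < 1
   ```

   evaluated on a voxel lattice and sliced into 5 equal-interval classes
   (classes 1–2 = strong clusters, 3 = weak).

Because police accident records are typically not public, the package
ships a synthetic scenario generator (`hotcube.synthetic`) that plants
known spatial clusters with configurable hour-of-day and month profiles
and two overlapping elderly subpopulations (drivers vs victims), so every
stage is testable against planted truth.

## Worked example

```python
from hotcube.pipeline import load_config, run_pipeline

cfg = load_config(overrides={"scenario": "seoul_like", "seed": 1,
                             "role": "driver", "out_dir": "demo"})
manifest = run_pipeline(cfg)
```

or equivalently `hotcube run --seed 1 --out demo` with
`scenario: seoul_like` and `role: driver` in a YAML config.  One run
(seed 1) prints a manifest containing:

```
load:      7303 events generated, 0 dropped
filter:    3319 elderly-driver events retained
kde:       radius_m = 1473.06  (plug-in rule on the driver subset)
hotspots:  cell 425 m, band 637.5 m, 148 cells hot99
cube:      totals 3319 in both the 24-hour and monthly cubes
emerging:  128 persistent, 25 sporadic, 4 intensifying, 2 diminishing,
           2 historical, 1 consecutive hotspot; 6838 cells no pattern
stkde:     peak voxel at (x, y, t) = (−5779 m, 8023 m, 1628 h)
```

Reading the numbers: the three planted driver clusters light up as dense
blocks of `hot99` cells; their year-round activity makes them *persistent*
hotspots in the monthly trend analysis; and the STKDE peak voxel sits on
the planted cluster at (−6000 m, 8000 m) — the densest locus in space and
time.  Artefacts (CSV/GeoJSON fields, the voxel volume as CSV and legacy
VTK, and `manifest.json` with SHA-256 hashes of every output) land in the
output directory; reruns with the same config and seed are byte-identical.

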