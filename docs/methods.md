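# Methods

This note documents the statistical procedures, parameter choices, and
numerical conventions behind `hotcube`, and what the synthetic test
scenarios do and do not establish about real data.

## Event model and coordinates

An event table is one row per incident: WGS84 coordinates, a naive local
timestamp (minute precision), and nullable driver/victim ages.  Rows with
out-of-range coordinates or unparseable timestamps are dropped and counted,
never silently.  Timestamps are treated as wall-clock local time in a
single fixed zone with no daylight-saving arithmetic — the analyses use
only the clock hour and the calendar month, for which civil clock time is
the quantity of interest.

All spatial statistics run in planar metres.  Because no projection
library is assumed, `hotcube.projection` implements the ellipsoidal
transverse-Mercator mapping (Krüger series to sixth order in the third
flattening, WGS84 constants) with standard UTM parameterisation
(`utm:<zone><N|S>`) or a local centred variant (`tm:<lon0>,<lat0>`).
Truncation error of the series is sub-millimetre at city scale and the
forward/inverse round trip reproduces coordinates to ~1e-14 degrees, far
inside the 1e-6-degree tolerance the event pipeline requires.  The
elderly-age threshold is ≥ 65 years (age exactly 65 included).

## Gridding

Cells are squares of side `cell_size` laid from the bounding-box minimum
corner.  Cell intervals are half-open `[lower, upper)` in x and y, with
the grid's outermost top/right boundary closed so hull points are kept.
Two independent cell-size rules coexist, mirroring common practice:

* hotspot grids use a fixed analysis cell (default 425 m, or the
  autocorrelation-peak scan below);
* space-time cubes use `longest_extent_side / 100` rounded to the nearest
  10 m (half rounds up), e.g. a 42 750 m side gives 430 m cells.

## Planar KDE

The plug-in search radius is
`0.9 · min(SD, √(1/ln 2) · D_m) · n^(−0.2)` with `SD` the root-mean-square
distance to the mean centre and `D_m` the **median** distance to the mean
centre.  `D_m` is sometimes glossed as an "average distance"; the median
is the standard choice and a `dm_stat="mean"` switch is provided, as is a
no-radical variant of the `1/ln 2` factor.  All point weights are 1 (one
event per point).  The kernel family is the quartic (biweight) kernel,
the common GIS default, normalised to unit planar integral so lattice mass
approximates `n`; Epanechnikov and Gaussian (σ = radius, truncated at 6σ)
are selectable.  Coincident-point degenerate configurations (SD = 0) are
an error rather than a zero bandwidth.

## Getis-Ord Gi* and the scale scan

Gi* uses binary distance-band weights on cell centroids, self-weight
included, and is computed over **all** `n` cells of the rectangular grid
(zero-count cells participate fully; an optional mask is future work).
Implementation is by dense correlation with the 0/1 stencil, which is
algebraically identical to the double loop; tests pin the equivalence to
1e-12.  Degenerate inputs (all cell values equal, or a variance term of
zero when a cell neighbours every cell) yield z = 0 with a warning rather
than NaN.  Confidence classes use |z| thresholds 1.65 / 1.96 / 2.58;
values exactly on a threshold take the more extreme class, closing the
open-interval gaps that would otherwise leave z = 2.58 unclassified.

The analysis scale is chosen by scanning candidate band distances and
returning the one maximising the global Moran's I z-score (incremental
spatial autocorrelation).  Moran's I uses row-standardised, self-excluded
distance-band weights and the analytical normality moments
(E[I] = −1/(n−1); variance from S0, S1, S2).  On a planted blob of radius
~2 cells over noise, the peak lands within one candidate step of the blob
scale.

## Space-time cubes and per-slice hotspots

The cyclic-hour cube has exactly 24 bins indexed by floor of the clock
hour (midnight wraps to 0); dates are deliberately discarded.  The
calendar-month cube uses the 12 months as-is, with their unequal lengths —
monthly bins mean calendar months, not 30-day windows.  Marginalising any
cube over time reproduces the plain 2D counts exactly.  Per-slice hotspot
fields apply spatial-only Gi* to each slice independently (no temporal
smoothing); display aggregation into e.g. two-hour reading windows is left
to the caller.

## Emerging-hotspot classification

Space-time Gi* extends the neighbourhood to the spatial band across time
bins `t−lag … t` (trailing window, default lag 1), with the statistic
computed over all space-time bins.  Per-cell trend uses the Mann-Kendall
test on the monthly count series: `S = Σ_{i<j} sign(a_j − a_i)`,
tie-corrected variance `[n(n−1)(2n+5) − Σ t(t−1)(2t+5)]/18`, ±1 continuity
correction, two-sided normal p-value, significance at α = 0.05.

The 17 labels follow the established emerging-hot-spot rule set, with
bin-level significance at the 90 % band (the most permissive of the three)
and a 90 % prevalence threshold, all configurable.  For a cell whose final
bin is significant on one side: ≥ 90 % of bins significant → intensifying /
persistent / diminishing by trend direction (mirrored for cold: falling
counts intensify a coldspot); otherwise any opposite-sign history →
oscillating; exactly one significant bin → new; a single unbroken trailing
run → consecutive; an interrupted history with no opposite sign →
sporadic.  A quiet final bin with ≥ 90 % of *earlier* bins significant →
historical.  Anything else is "no pattern".  The hot side is evaluated
before the cold side; the two cannot both match because a bin cannot be
simultaneously hot and cold and the prevalence thresholds cannot both be
met.  Labels are invariant under positive scaling of all counts.

## STKDE

The estimator and both kernels are implemented exactly as stated in the
README, with time measured in hours since the span start.  The default
parameters target a month-scale urban analysis: `h_s` = 1000 m,
`h_t` = 720 h (≈ one month).  The `scale_factor` (default 1e10) is pure
presentation scaling — with `scale_factor = 1` the voxel Riemann sum
converges to 1 — and linearity in it is tested.  Evaluation scatters each
event onto the voxels inside its compact support; this is exactly the
naive voxel × event triple loop reordered, and tests pin agreement at
relative 1e-12.  Default lattice spacing is bandwidth/4 in each axis
(250 m, 180 h), a compromise between argmax localisation and volume size.

Equal-interval classification splits `[min, max]` intensity into five
equal widths with **class 1 the highest-density interval**, so the
convention "classes 1–2 = strong clusters, class 3 = weak" reads
naturally; the opposite ordering would invert the strength labels, and the
choice is confined to `classify_equal_interval`.  Constant volumes
degenerate to class 5 with a warning.  Volumes export as a lossless
x,y,t,intensity,class CSV and as VTK legacy ASCII structured points (text
format, uniform spacing required) for 3D viewers.

## Synthetic scenarios

The generator emulates one year of city-scale accident data: a uniform
spatiotemporal background over a 42 750 × 30 000 m extent plus Gaussian
spatial clusters with wrapped-normal hour mixtures (chosen over von Mises
for simple inverse-transform sampling) and categorical month weights.
Cluster counts are Poisson around their means; ages are uniform integers —
background 20–90 for both roles, cluster events 65–90 for the tagged role
and 20–64 for the other, so each cluster feeds exactly one analysis
subset.  Planted truth (cluster id per row) is written to a sidecar table
so the main CSV looks like real data.  Generation is deterministic given
the seed (NumPy PCG64).

The `seoul_like` preset plants three northern "driver" loci active
morning-to-afternoon and five dispersed "victim" loci active
daytime-to-evening, two of them seasonal ("mountain" loci with month
weights peaking April–May and September–October).  Expected subset sizes
are ≈ 3 300 elderly-driver and ≈ 3 590 elderly-victim events (background
contributes ≈ 26/71 × 2 000 to each).  What the passing tests show: the
pipeline recovers planted spatial clusters (hot99 cores), their diurnal
and seasonal activity windows, and the space-time density peak, at
realistic event counts.  What they do not show: behaviour under
road-network-constrained geometry, geocoding error, heaped or missing
timestamps, population-at-risk confounding, or multi-year drift — real
accident data have all of these.

## Problem sizes and determinism

Test and demonstration runs use the preset's ≈ 7 300 events on grids of
roughly 100 × 70 cells (425–430 m), 24- or 12-bin time axes, and STKDE
lattices near 86 × 61 × 37 voxels (500 m / 240 h spacing in the recovery
tests) — sizes at which every stage completes in seconds while leaving the
planted-structure recovery statistically unambiguous.  The repeated-seed
acceptance checks run 100 independent replicates.  All randomness flows
from explicit integer seeds; pipeline manifests record SHA-256 hashes of
every artefact, and identical config + seed reproduces byte-identical
outputs.

## Known limitations

* Rectangular study extents only; no polygon mask for Gi*'s `n` (all
  grid cells participate).
* No false-discovery-rate correction across cells, matching common
  practice for these map products; interpret isolated 90 % cells with
  care.
* STKDE has no edge correction; densities within one bandwidth of the
  data hull or span ends are biased low.
* The ESRI-style "no pattern due to low counts" pre-filter is not
  implemented; sparse cells rely on the Gi* significance gates alone.
* KDE surfaces export as CSV lattices and GeoJSON, not GeoTIFF rasters.
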