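"""Getis-Ord Gi* hot/cold-spot statistics on gridded counts.

The local statistic for cell i over the n cells of the grid is

    z_i = [ sum_j w_ij x_j  -  Xbar * W_i ]
          / ( S * sqrt( (n * sum_j w_ij^2 - W_i^2) / (n - 1) ) )

with binary distance-band weights w_ij in {0, 1} (self-weight 1 for the
starred statistic), W_i = sum_j w_ij, Xbar = sum_j x_j / n and
S = sqrt(sum_j x_j^2 / n - Xbar^2).  z_i is asymptotically standard
normal under spatial randomness; the usual 90/95/99% confidence bands map
z to hot/cold classes.  All n cells of the rectangular grid participate,
including zero-count cells.

The module also implements the incremental-spatial-autocorrelation scan
(global Moran's I z-score over a ladder of band distances) used to pick
the analysis scale: the band with the peak z-score marks the distance at
which spatial processes are most active.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import CellCounts, GridSpec, counts_to_geojson

logger = logging.getLogger(__name__)

#: confidence classes ordered cold to hot
CONFIDENCE_CLASSES = ("cold99", "cold95", "cold90", "none",
                      "hot90", "hot95", "hot99")

#: z thresholds of the 90/95/99% two-sided confidence bands
Z90, Z95, Z99 = 1.65, 1.96, 2.58


@dataclass
class WeightsMatrix:
    """Binary distance-band weights between grid-cell centroids.

    ``offsets`` lists the (drow, dcol) displacements whose centroid
    distance is within ``band`` metres; ``footprint`` is the equivalent
    dense 0/1 stencil for convolution.  The neighbour relation is
    symmetric by construction.
    """

    grid: GridSpec
    band: float
    include_self: bool
    offsets: np.ndarray
    footprint: np.ndarray

    def neighbors(self, row: int, col: int) -> list[tuple[int, int]]:
        """In-grid neighbour cells of (row, col), including itself when
        the self-inclusion flag is set."""
        out = []
        for dr, dc in self.offsets:
            r, c = row + dr, col + dc
            if 0 <= r < self.grid.n_rows and 0 <= c < self.grid.n_cols:
                out.append((int(r), int(c)))
        return out


def build_weights(grid: GridSpec, band: float, include_self: bool = True) -> WeightsMatrix:
    """Distance-band weights: w_ij = 1 iff centroid distance <= band
    (plus i = j when ``include_self``)."""
    if band <= 0:
        raise ValueError(f"band must be positive, got {band}")
    reach = int(np.floor(band / grid.cell_size + 1e-9))
    dr, dc = np.meshgrid(np.arange(-reach, reach + 1),
                         np.arange(-reach, reach + 1), indexing="ij")
    dist = np.hypot(dr, dc) * grid.cell_size
    mask = dist <= band * (1 + 1e-12)
    if not include_self:
        mask[reach, reach] = False
    offsets = np.stack([dr[mask], dc[mask]], axis=1)
    return WeightsMatrix(grid=grid, band=band, include_self=include_self,
                         offsets=offsets, footprint=mask.astype(float))


@dataclass
class GiField:
    """Per-cell Gi* z-scores with confidence classes on a grid."""

    grid: GridSpec
    z: np.ndarray
    classes: np.ndarray  # array of strings from CONFIDENCE_CLASSES


def classify_confidence(z):
    """Map z-scores to hot/cold confidence classes.

    Thresholds are inclusive toward the more extreme class: z = 2.58 is
    ``hot99``, z = -1.65 is ``cold90``.  NaN raises.
    """
    z = np.asarray(z, dtype=float)
    if np.isnan(z).any():
        raise ValueError("z contains NaN")
    out = np.full(z.shape, "none", dtype=object)
    out[z >= Z90] = "hot90"
    out[z >= Z95] = "hot95"
    out[z >= Z99] = "hot99"
    out[z <= -Z90] = "cold90"
    out[z <= -Z95] = "cold95"
    out[z <= -Z99] = "cold99"
    return out if out.ndim else out.item()


def _gi_star_array(x: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Gi* z-scores for a 2D (or nD) value array with a 0/1 stencil.

    Cells outside the array contribute nothing (W_i shrinks at edges).
    Degenerate inputs (all values equal) give z = 0 everywhere.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 cells")
    xbar = x.sum() / n
    s = np.sqrt(max(0.0, (x**2).sum() / n - xbar**2))
    lag = ndimage.correlate(x, footprint, mode="constant", cval=0.0)
    w_i = ndimage.correlate(np.ones_like(x), footprint, mode="constant", cval=0.0)
    # binary weights: sum_j w_ij^2 = W_i
    var_term = (n * w_i - w_i**2) / (n - 1)
    denom = s * np.sqrt(np.maximum(var_term, 0.0))
    z = np.zeros_like(x)
    if s == 0.0:
        logger.warning("gi_star: all cell values equal; z set to 0 everywhere")
        return z
    ok = denom > 0
    z[ok] = (lag[ok] - xbar * w_i[ok]) / denom[ok]
    if not ok.all():
        logger.warning("gi_star: %d cells with undefined variance term set to z=0",
                       int((~ok).sum()))
    return z


def gi_star(values: CellCounts, weights: WeightsMatrix) -> GiField:
    """Getis-Ord Gi* field over all cells of the grid."""
    z = _gi_star_array(values.counts, weights.footprint)
    return GiField(grid=values.grid, z=z, classes=classify_confidence(z))


@dataclass
class MoranResult:
    """Global Moran's I with its analytical-normality z-score."""

    i: float
    expected: float
    variance: float
    z: float


def morans_i(values: CellCounts, band: float) -> MoranResult:
    """Global Moran's I with row-standardised distance-band weights.

    Weights exclude self; rows with no neighbour get zero weights.  The
    z-score uses the analytical expectation -1/(n-1) and the normality
    variance (n^2 S1 - n S2 + 3 S0^2) / (S0^2 (n^2 - 1)) - E[I]^2.
    """
    x = values.counts.astype(float)
    n = x.size
    dev = x - x.mean()
    ss = (dev**2).sum()
    if ss == 0:
        raise ValueError("Moran's I undefined: all cell values equal")
    w = build_weights(values.grid, band, include_self=False)
    fp = w.footprint
    k = ndimage.correlate(np.ones_like(x), fp, mode="constant", cval=0.0)
    has = k > 0
    inv_k = np.zeros_like(x)
    inv_k[has] = 1.0 / k[has]
    # numerator sum_ij w_ij z_i z_j with w_ij = 1/k_i
    lag = ndimage.correlate(dev, fp, mode="constant", cval=0.0)
    num = float((inv_k * dev * lag).sum())
    s0 = float(has.sum())  # row sums are 1 where a neighbour exists
    # S1 = 1/2 sum over ordered pairs (w_ij + w_ji)^2, S2 = sum_i (r_i + c_i)^2
    s1 = 0.0
    nr, nc = x.shape
    for dr, dc in w.offsets:
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = inv_k[r0:r1, c0:c1]
        b = inv_k[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        s1 += 0.5 * float(((a + b) ** 2).sum())
    col_sums = ndimage.correlate(inv_k, fp, mode="constant", cval=0.0)
    row_sums = has.astype(float)
    s2 = float(((row_sums + col_sums) ** 2).sum())

    i_val = (n / s0) * num / ss
    e_i = -1.0 / (n - 1)
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - e_i**2
    z = (i_val - e_i) / np.sqrt(var)
    return MoranResult(i=i_val, expected=e_i, variance=var, z=float(z))


def peak_autocorr_distance(values: CellCounts, candidate_bands) -> float:
    """Band distance with the maximum Moran's I z-score.

    Scans ``candidate_bands`` (metres) and returns the one whose global
    autocorrelation z peaks — the scale at which clustering is most
    pronounced, used to choose the hotspot cell/band size.
    """
    bands = list(candidate_bands)
    if not bands:
        raise ValueError("need at least one candidate band")
    if np.ptp(values.counts) == 0:
        raise ValueError("Moran's I undefined: all cell values equal")
    if len(bands) == 1:
        return float(bands[0])
    zs = [morans_i(values, b).z for b in bands]
    return float(bands[int(np.argmax(zs))])


def gi_field_to_csv(field: GiField, path) -> None:
    """Write the Gi* field as CSV columns row, col, z, class."""
    rows, cols = np.indices(field.z.shape)
    pd.DataFrame({"row": rows.ravel(), "col": cols.ravel(),
                  "z": field.z.ravel(),
                  "class": field.classes.ravel()}).to_csv(path, index=False)


def gi_field_to_geojson(field: GiField, counts: CellCounts, path) -> None:
    """Write cells as GeoJSON polygons with count, z and class properties."""
    counts_to_geojson(counts, path,
                      attributes={"z": field.z, "class": field.classes})
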