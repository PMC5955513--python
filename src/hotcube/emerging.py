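"""Emerging-hotspot trend classification over a space-time cube.

Each cell's history of space-time Gi* significance, together with a
Mann-Kendall monotone-trend test on its count series, is mapped to one of
17 labels: {new, consecutive, intensifying, persistent, diminishing,
sporadic, oscillating, historical} x {hotspot, coldspot}, plus
"no pattern".  The decision rules follow the established
emerging-hot-spot-analysis definitions: bin-level significance at the 90%
confidence band, a 90% prevalence threshold for "most of the history",
and the final bin's status driving the hot/cold side.  All thresholds are
arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import erf, sqrt

import numpy as np
import pandas as pd

from .cube import SpaceTimeCube
from .gistar import Z90, WeightsMatrix, _gi_star_array
from .grid import GridSpec

logger = logging.getLogger(__name__)

_BASES = ("new", "consecutive", "intensifying", "persistent",
          "diminishing", "sporadic", "oscillating", "historical")


def category_vocabulary() -> tuple[str, ...]:
    """The fixed 17-label trend vocabulary."""
    labels = [f"{b} hotspot" for b in _BASES] + [f"{b} coldspot" for b in _BASES]
    labels.append("no pattern")
    return tuple(labels)


@dataclass
class MannKendallResult:
    """Mann-Kendall monotone-trend test result for one series."""

    s: int
    var_s: float
    z: float
    p: float
    direction: str  # "up" | "down" | "none"


def mann_kendall(series, alpha: float = 0.05) -> MannKendallResult:
    """Mann-Kendall trend test with tie-corrected variance.

    S = sum over pairs i<j of sign(a_j - a_i); Var(S) uses the tie
    correction sum t(t-1)(2t+5); z applies the +/-1 continuity
    correction; ``direction`` is "up"/"down" when the two-sided p-value
    is at or below ``alpha``, else "none".  Needs at least 3 values.
    """
    a = np.asarray(series, dtype=float)
    n = len(a)
    if n < 3:
        raise ValueError(f"Mann-Kendall needs at least 3 values, got {n}")
    diff = np.sign(a[None, :] - a[:, None])
    s = int(np.triu(diff, k=1).sum())
    _, tie_counts = np.unique(a, return_counts=True)
    ties = tie_counts[tie_counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5)
             - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:  # all values identical
        return MannKendallResult(s=0, var_s=0.0, z=0.0, p=1.0, direction="none")
    if s > 0:
        z = (s - 1) / sqrt(var_s)
    elif s < 0:
        z = (s + 1) / sqrt(var_s)
    else:
        z = 0.0
    p = 2.0 * (1.0 - 0.5 * (1.0 + erf(abs(z) / sqrt(2.0))))
    if p <= alpha and s != 0:
        direction = "up" if s > 0 else "down"
    else:
        direction = "none"
    return MannKendallResult(s=s, var_s=float(var_s), z=float(z), p=float(p),
                             direction=direction)


def st_gi_star(cube: SpaceTimeCube, weights: WeightsMatrix,
               time_lag: int = 1) -> np.ndarray:
    """Space-time Gi* z tensor ``[row, col, t]``.

    The neighbourhood of bin (i, t) is the spatial distance-band
    neighbourhood of cell i taken across time bins t-lag .. t (past bins
    only), and the Gi* formula is applied over the full set of space-time
    bins (n = rows x cols x nt).  A degenerate cube (all bins equal)
    yields a zero tensor with a warning.
    """
    if cube.n_time_bins < 2 and time_lag > 0:
        raise ValueError("space-time Gi* needs at least 2 time bins")
    if time_lag < 0:
        raise ValueError("time_lag must be >= 0")
    fp2 = weights.footprint
    nt_k = 2 * time_lag + 1
    fp3 = np.zeros(fp2.shape + (nt_k,))
    for i in range(time_lag + 1):  # offsets -lag .. 0 on the time axis
        fp3[:, :, i] = fp2
    return _gi_star_array(cube.counts.astype(float), fp3)


@dataclass
class TrendField:
    """Per-cell 17-way trend labels with the per-cell Mann-Kendall z."""

    grid: GridSpec
    labels: np.ndarray  # object array of strings, shape (n_rows, n_cols)
    mk_z: np.ndarray


def _classify_history(sig: np.ndarray, opp: np.ndarray, trend: str,
                      prevalence: float) -> str | None:
    """Label one side (hot or cold) of a cell's significance history.

    ``sig``/``opp`` are per-bin booleans for this side and the opposite
    side; ``trend`` is the count-trend direction already mapped so that
    "up" means intensifying for this side.  Returns the base label or
    None when this side shows no pattern.
    """
    nb = len(sig)
    frac = sig.mean()
    if sig[-1]:
        if frac >= prevalence:
            if trend == "up":
                return "intensifying"
            if trend == "down":
                return "diminishing"
            return "persistent"
        if opp.any():
            return "oscillating"
        if sig.sum() == 1:
            return "new"
        # trailing run of significant bins ending at the final bin
        run = 1
        while run < nb and sig[-1 - run]:
            run += 1
        if sig[:nb - run].any():
            return "sporadic"
        return "consecutive"
    if nb > 1 and sig[:-1].mean() >= prevalence:
        return "historical"
    return None


def classify_emerging(z_tensor: np.ndarray, cube: SpaceTimeCube,
                      alpha: float = 0.05, prevalence: float = 0.90,
                      sig_z: float = Z90) -> TrendField:
    """Assign each cell one of the 17 trend labels.

    Per-bin hot/cold flags come from the space-time Gi* z at the 90%
    confidence threshold (``sig_z``); the count trend per cell is the
    Mann-Kendall direction at level ``alpha``.  The hot side is evaluated
    first; a cell with neither side patterned is "no pattern".
    """
    if z_tensor.shape != cube.counts.shape:
        raise ValueError(f"z tensor shape {z_tensor.shape} does not match "
                         f"cube shape {cube.counts.shape}")
    nr, nc, _ = cube.counts.shape
    labels = np.full((nr, nc), "no pattern", dtype=object)
    mk_z = np.zeros((nr, nc))
    for r in range(nr):
        for c in range(nc):
            hot = z_tensor[r, c, :] >= sig_z
            cold = z_tensor[r, c, :] <= -sig_z
            mk = mann_kendall(cube.counts[r, c, :], alpha=alpha)
            mk_z[r, c] = mk.z
            base = _classify_history(hot, cold, mk.direction, prevalence)
            if base is not None:
                labels[r, c] = f"{base} hotspot"
                continue
            flipped = {"up": "down", "down": "up"}.get(mk.direction, "none")
            base = _classify_history(cold, hot, flipped, prevalence)
            if base is not None:
                labels[r, c] = f"{base} coldspot"
    return TrendField(grid=cube.grid, labels=labels, mk_z=mk_z)


def trend_field_to_csv(field: TrendField, path) -> None:
    """Write trend labels as CSV columns row, col, label, mk_z."""
    rows, cols = np.indices(field.labels.shape)
    pd.DataFrame({"row": rows.ravel(), "col": cols.ravel(),
                  "label": field.labels.ravel(),
                  "mk_z": field.mk_z.ravel()}).to_csv(path, index=False)


def trend_field_to_geojson(field: TrendField, path) -> None:
    """Write cells as GeoJSON polygons with label and mk_z properties."""
    import json

    feats = []
    for r in range(field.grid.n_rows):
        for c in range(field.grid.n_cols):
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Polygon",
                             "coordinates": [field.grid.cell_polygon(r, c)]},
                "properties": {"row": r, "col": c,
                               "label": str(field.labels[r, c]),
                               "mk_z": float(field.mk_z[r, c])},
            })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
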