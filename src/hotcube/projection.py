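"""Planar map projections for event coordinates.

All downstream analysis (gridding, kernel densities, hotspot statistics)
operates in metres, so WGS84 longitude/latitude pairs are projected onto a
transverse-Mercator plane first.  The implementation is the ellipsoidal
Krüger series (6th order in the third flattening), the same formulation
used by UTM; forward/inverse round-trip error is far below 1e-6 degrees
over any city-scale extent.

CRS tags
--------
``"utm:52N"``
    Standard UTM zone (central meridian ``6*zone - 183``, scale 0.9996,
    false easting 500 km; southern zones add a 10 000 km false northing).
``"tm:<lon0>,<lat0>"``
    Local transverse Mercator centred on ``(lon0, lat0)``: the centre maps
    to ``(0, 0)`` metres.  Convenient for synthetic extents.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

# WGS84
_A = 6378137.0
_F = 1.0 / 298.257223563


def _kruger_coefficients(n: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Series coefficients (alpha, beta, delta) to 6th order in n."""
    n2, n3, n4, n5, n6 = n**2, n**3, n**4, n**5, n**6
    alpha = np.array([
        n / 2 - 2 * n2 / 3 + 5 * n3 / 16 + 41 * n4 / 180 - 127 * n5 / 288 + 7891 * n6 / 37800,
        13 * n2 / 48 - 3 * n3 / 5 + 557 * n4 / 1440 + 281 * n5 / 630 - 1983433 * n6 / 1935360,
        61 * n3 / 240 - 103 * n4 / 140 + 15061 * n5 / 26880 + 167603 * n6 / 181440,
        49561 * n4 / 161280 - 179 * n5 / 168 + 6601661 * n6 / 7257600,
        34729 * n5 / 80640 - 3418889 * n6 / 1995840,
        212378941 * n6 / 319334400,
    ])
    beta = np.array([
        n / 2 - 2 * n2 / 3 + 37 * n3 / 96 - n4 / 360 - 81 * n5 / 512 + 96199 * n6 / 604800,
        n2 / 48 + n3 / 15 - 437 * n4 / 1440 + 46 * n5 / 105 - 1118711 * n6 / 3870720,
        17 * n3 / 480 - 37 * n4 / 840 - 209 * n5 / 4480 + 5569 * n6 / 90720,
        4397 * n4 / 161280 - 11 * n5 / 504 - 830251 * n6 / 7257600,
        4583 * n5 / 161280 - 108847 * n6 / 3991680,
        20648693 * n6 / 638668800,
    ])
    delta = np.array([
        2 * n - 2 * n2 / 3 - 2 * n3 + 116 * n4 / 45 + 26 * n5 / 45 - 2854 * n6 / 675,
        7 * n2 / 3 - 8 * n3 / 5 - 227 * n4 / 45 + 2704 * n5 / 315 + 2323 * n6 / 945,
        56 * n3 / 15 - 136 * n4 / 35 - 1262 * n5 / 105 + 73814 * n6 / 2835,
        4279 * n4 / 630 - 332 * n5 / 35 - 399572 * n6 / 14175,
        4174 * n5 / 315 - 144838 * n6 / 6237,
        601676 * n6 / 22275,
    ])
    return alpha, beta, delta


@dataclass
class TransverseMercator:
    """Ellipsoidal transverse-Mercator projection (WGS84)."""

    lon0: float
    k0: float = 0.9996
    false_easting: float = 0.0
    false_northing: float = 0.0
    tag: str = ""
    _alpha: np.ndarray = field(init=False, repr=False)
    _beta: np.ndarray = field(init=False, repr=False)
    _delta: np.ndarray = field(init=False, repr=False)
    _rect_a: float = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = _F / (2.0 - _F)
        self._alpha, self._beta, self._delta = _kruger_coefficients(n)
        self._rect_a = _A / (1.0 + n) * (1.0 + n**2 / 4.0 + n**4 / 64.0 + n**6 / 256.0)

    def forward(self, lon, lat):
        """(lon, lat) degrees -> (x, y) metres."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        phi = np.radians(lat)
        lam = np.radians(lon - self.lon0)
        e = np.sqrt(_F * (2.0 - _F))
        # conformal latitude
        t = np.sinh(np.arctanh(np.sin(phi)) - e * np.arctanh(e * np.sin(phi)))
        xi_p = np.arctan2(t, np.cos(lam))
        eta_p = np.arcsinh(np.sin(lam) / np.hypot(t, np.cos(lam)))
        xi = xi_p.copy()
        eta = eta_p.copy()
        for j, a in enumerate(self._alpha, start=1):
            xi = xi + a * np.sin(2 * j * xi_p) * np.cosh(2 * j * eta_p)
            eta = eta + a * np.cos(2 * j * xi_p) * np.sinh(2 * j * eta_p)
        x = self.false_easting + self.k0 * self._rect_a * eta
        y = self.false_northing + self.k0 * self._rect_a * xi
        return x, y

    def inverse(self, x, y):
        """(x, y) metres -> (lon, lat) degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xi = (y - self.false_northing) / (self.k0 * self._rect_a)
        eta = (x - self.false_easting) / (self.k0 * self._rect_a)
        xi_p = xi.copy()
        eta_p = eta.copy()
        for j, b in enumerate(self._beta, start=1):
            xi_p = xi_p - b * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
            eta_p = eta_p - b * np.cos(2 * j * xi) * np.sinh(2 * j * eta)
        chi = np.arcsin(np.sin(xi_p) / np.cosh(eta_p))
        phi = chi.copy()
        for j, d in enumerate(self._delta, start=1):
            phi = phi + d * np.sin(2 * j * chi)
        lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))
        return np.degrees(lam) + self.lon0, np.degrees(phi)


_UTM_RE = re.compile(r"^utm:(\d{1,2})([NS])$", re.IGNORECASE)
_TM_RE = re.compile(r"^tm:(-?\d+(?:\.\d+)?),(-?\d+(?:\.\d+)?)$")


def parse_crs(crs_tag: str) -> TransverseMercator:
    """Build a projection from a CRS tag (see module docstring).

    Raises ``ValueError`` for an unrecognised tag.
    """
    m = _UTM_RE.match(crs_tag)
    if m:
        zone = int(m.group(1))
        if not 1 <= zone <= 60:
            raise ValueError(f"UTM zone out of range: {zone}")
        south = m.group(2).upper() == "S"
        return TransverseMercator(
            lon0=6.0 * zone - 183.0,
            k0=0.9996,
            false_easting=500_000.0,
            false_northing=10_000_000.0 if south else 0.0,
            tag=crs_tag,
        )
    m = _TM_RE.match(crs_tag)
    if m:
        lon0, lat0 = float(m.group(1)), float(m.group(2))
        proj = TransverseMercator(lon0=lon0, tag=crs_tag)
        x0, y0 = proj.forward(lon0, lat0)
        proj.false_easting = -float(x0)
        proj.false_northing = -float(y0)
        return proj
    raise ValueError(
        f"unknown crs_tag {crs_tag!r}; expected 'utm:<zone><N|S>' or 'tm:<lon0>,<lat0>'"
    )
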