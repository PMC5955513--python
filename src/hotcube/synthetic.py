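"""Synthetic accident-like event generator with known planted structure.

Real police accident records are not public, so every pipeline stage is
exercised on generated tables that emulate their structure: a city-scale
extent (~43 km across), a one-year span, a uniform background of events,
and Gaussian spatial clusters whose hour-of-day profiles (wrapped-normal
mixtures), month weights, and role-specific ages (elderly drivers vs
elderly victims) are all known to the tests.

The generated CSV uses the exact schema :func:`hotcube.events.read_events`
expects; the cluster membership of every row (the planted truth) goes to a
sidecar table so pipeline inputs look like real data.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .projection import parse_crs

_SECONDS_PER_DAY = 86400


@dataclass
class ClusterConfig:
    """One planted space-time cluster.

    ``center`` is in scenario-local planar metres; ``sigma`` the spatial
    Gaussian spread; ``hour_peaks`` a wrapped-normal mixture of
    ``(mean_hour, sigma_hours, weight)``; ``month_weights`` 12 relative
    probabilities (Jan..Dec); ``n_mean`` the expected event count (drawn
    Poisson); ``role`` marks which participant is elderly.
    """

    name: str
    center: tuple[float, float]
    sigma: float
    hour_peaks: tuple = ((12.0, 6.0, 1.0),)
    month_weights: tuple = (1.0,) * 12
    n_mean: float = 100.0
    role: str = "driver"

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"cluster {self.name}: sigma must be positive")
        if self.n_mean < 0:
            raise ValueError(f"cluster {self.name}: n_mean must be >= 0")
        if self.role not in ("driver", "victim"):
            raise ValueError(f"cluster {self.name}: unknown role {self.role!r}")
        if len(self.month_weights) != 12 or min(self.month_weights) < 0 \
                or sum(self.month_weights) <= 0:
            raise ValueError(f"cluster {self.name}: invalid month_weights")
        if not self.hour_peaks or min(w for _, _, w in self.hour_peaks) < 0 \
                or sum(w for _, _, w in self.hour_peaks) <= 0 \
                or min(s for _, s, _ in self.hour_peaks) <= 0:
            raise ValueError(f"cluster {self.name}: invalid hour_peaks")


@dataclass
class ScenarioConfig:
    """Study-area extent, background intensity, and planted clusters.

    The extent is centred on the local projection origin (``crs_tag``), so
    planar coordinates run from ``-width/2`` to ``width/2``.  Background
    events are uniform over space, the year, and the 24-hour clock, with
    ages uniform on 20..90 for both roles.
    """

    width: float = 42_750.0
    height: float = 30_000.0
    n_background: int = 2_000
    clusters: tuple = ()
    year: int = 2013
    crs_tag: str = "tm:127.0,37.55"
    seed: int = 0
    age_range: tuple[int, int] = (20, 90)
    elderly_age_range: tuple[int, int] = (65, 90)

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("extent must be positive")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        for c in self.clusters:
            if not isinstance(c, ClusterConfig):
                raise ValueError("clusters must be ClusterConfig instances")


def hour_bin_probabilities(cluster: ClusterConfig) -> np.ndarray:
    """Probability of each hour-of-day bin 0..23 under the cluster's
    wrapped-normal hour mixture (used by goodness-of-fit checks)."""
    from scipy.stats import norm

    edges = np.arange(25.0)
    p = np.zeros(24)
    wsum = sum(w for _, _, w in cluster.hour_peaks)
    for mu, sig, w in cluster.hour_peaks:
        for k in range(-4, 5):  # unwrap the circle
            p += (w / wsum) * (norm.cdf(edges[1:], mu + 24 * k, sig)
                               - norm.cdf(edges[:-1], mu + 24 * k, sig))
    return p / p.sum()


def month_probabilities(cluster: ClusterConfig) -> np.ndarray:
    w = np.asarray(cluster.month_weights, float)
    return w / w.sum()


def _random_timestamps_uniform(rng, year: int, n: int) -> pd.Series:
    days = 366 if calendar.isleap(year) else 365
    sec = rng.uniform(0, days * _SECONDS_PER_DAY, size=n)
    base = pd.Timestamp(f"{year}-01-01")
    ts = base + pd.to_timedelta(np.floor(sec / 60.0) * 60, unit="s")
    return pd.Series(ts)


def _cluster_timestamps(rng, year: int, cluster: ClusterConfig, n: int) -> pd.Series:
    months = rng.choice(12, size=n, p=month_probabilities(cluster)) + 1
    days_in = np.array([calendar.monthrange(year, m)[1] for m in range(1, 13)])
    day = rng.integers(1, days_in[months - 1] + 1)
    peaks = cluster.hour_peaks
    wsum = sum(w for _, _, w in peaks)
    comp = rng.choice(len(peaks), size=n, p=[w / wsum for _, _, w in peaks])
    mus = np.array([p[0] for p in peaks])
    sigs = np.array([p[1] for p in peaks])
    hour_f = (rng.normal(mus[comp], sigs[comp])) % 24.0
    hh = np.floor(hour_f).astype(int)
    mm = np.floor((hour_f - hh) * 60).astype(int)
    return pd.Series(pd.to_datetime({
        "year": np.full(n, year), "month": months, "day": day,
        "hour": hh, "minute": mm}))


def generate_scenario(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one event table (and its truth sidecar) from a scenario.

    Returns ``(events, truth)``: ``events`` in the canonical schema with
    WGS84 coordinates obtained by inverse-projecting the planar samples;
    ``truth`` row-aligned with columns ``event_id``, ``cluster`` (cluster
    name or ``"background"``), ``x``, ``y`` (planar metres).  Cluster
    counts are Poisson around ``n_mean``; spatial samples falling outside
    the extent are redrawn.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    half_w, half_h = config.width / 2.0, config.height / 2.0
    lo_age, hi_age = config.age_range
    lo_eld, hi_eld = config.elderly_age_range

    parts = []
    # background: uniform in space, the year, and ages
    nb = config.n_background
    bg = pd.DataFrame({
        "x": rng.uniform(-half_w, half_w, nb),
        "y": rng.uniform(-half_h, half_h, nb),
        "timestamp": _random_timestamps_uniform(rng, config.year, nb),
        "driver_age": rng.integers(lo_age, hi_age + 1, nb).astype(float),
        "victim_age": rng.integers(lo_age, hi_age + 1, nb).astype(float),
        "cluster": "background",
    })
    parts.append(bg)

    for cl in config.clusters:
        n = int(rng.poisson(cl.n_mean))
        cx, cy = cl.center
        x = rng.normal(cx, cl.sigma, n)
        y = rng.normal(cy, cl.sigma, n)
        for _ in range(100):  # redraw samples outside the extent
            bad = (np.abs(x) > half_w) | (np.abs(y) > half_h)
            if not bad.any():
                break
            x[bad] = rng.normal(cx, cl.sigma, int(bad.sum()))
            y[bad] = rng.normal(cy, cl.sigma, int(bad.sum()))
        # the tagged role is elderly; the other participant is non-elderly,
        # so each cluster feeds exactly one of the two analysis subsets
        elderly = rng.integers(lo_eld, hi_eld + 1, n).astype(float)
        other = rng.integers(lo_age, min(hi_age, lo_eld - 1) + 1, n).astype(float)
        parts.append(pd.DataFrame({
            "x": x, "y": y,
            "timestamp": _cluster_timestamps(rng, config.year, cl, n),
            "driver_age": elderly if cl.role == "driver" else other,
            "victim_age": elderly if cl.role == "victim" else other,
            "cluster": cl.name,
        }))

    table = pd.concat(parts, ignore_index=True)
    perm = rng.permutation(len(table))
    table = table.iloc[perm].reset_index(drop=True)

    proj = parse_crs(config.crs_tag)
    lon, lat = proj.inverse(table["x"].to_numpy(), table["y"].to_numpy())
    ids = [f"evt{i:06d}" for i in range(len(table))]
    events = pd.DataFrame({
        "event_id": ids,
        "lon": np.round(lon, 7), "lat": np.round(lat, 7),
        "timestamp": table["timestamp"],
        "driver_age": table["driver_age"], "victim_age": table["victim_age"],
        "gender": rng.choice(["F", "M"], len(table)),
        "weather": rng.choice(["clear", "cloudy", "rain", "snow"],
                              len(table), p=[0.55, 0.25, 0.15, 0.05]),
    })
    truth = pd.DataFrame({"event_id": ids, "cluster": table["cluster"],
                          "x": table["x"], "y": table["y"]})
    return events, truth


def write_scenario(events: pd.DataFrame, truth: pd.DataFrame,
                   events_path, truth_path=None) -> None:
    """Write the event CSV (canonical schema) and, optionally, the truth
    sidecar CSV."""
    from .events import write_events

    write_events(events, events_path)
    if truth_path is not None:
        truth.to_csv(truth_path, index=False)


_SEASONAL = (2, 2, 5, 10, 10, 4, 2, 2, 10, 10, 5, 2)  # Apr-May & Sep-Oct peaks


def seoul_like_preset(seed: int = 0) -> ScenarioConfig:
    """A documented preset shaped like one year of elderly-involved urban
    accidents in a large capital.

    About 3,300 expected elderly-driver and 3,590 expected elderly-victim
    events: a shared uniform background of 2,000 (ages uniform 20-90, so
    ~26/71 of it is elderly in each role) plus driver clusters at three
    northern loci active in the morning-to-afternoon hours and victim
    clusters at five dispersed loci active from daytime to evening, two of
    which ("mountain" loci) carry month weights peaking in April-May and
    September-October.
    """
    drv_hours = ((8.0, 1.5, 0.6), (14.0, 2.0, 0.4))
    vic_hours = ((11.0, 2.0, 0.5), (16.0, 2.5, 0.5))
    clusters = (
        ClusterConfig("driver_north_west", (-6_000.0, 8_000.0), 600.0,
                      hour_peaks=drv_hours, n_mean=1_000, role="driver"),
        ClusterConfig("driver_north_mid", (2_000.0, 10_000.0), 700.0,
                      hour_peaks=drv_hours, n_mean=900, role="driver"),
        ClusterConfig("driver_north_east", (9_000.0, 7_000.0), 600.0,
                      hour_peaks=((9.0, 1.5, 0.5), (15.0, 2.0, 0.5)),
                      n_mean=668, role="driver"),
        ClusterConfig("victim_mountain_north", (-3_000.0, 13_500.0), 700.0,
                      hour_peaks=vic_hours, month_weights=_SEASONAL,
                      n_mean=700, role="victim"),
        ClusterConfig("victim_mountain_east", (12_000.0, 12_000.0), 700.0,
                      hour_peaks=vic_hours, month_weights=_SEASONAL,
                      n_mean=600, role="victim"),
        ClusterConfig("victim_west", (-12_000.0, 4_000.0), 800.0,
                      hour_peaks=vic_hours, n_mean=550, role="victim"),
        ClusterConfig("victim_central", (5_000.0, 2_000.0), 800.0,
                      hour_peaks=vic_hours, n_mean=500, role="victim"),
        ClusterConfig("victim_south", (-2_000.0, -8_000.0), 900.0,
                      hour_peaks=((13.0, 2.5, 0.5), (18.0, 2.0, 0.5)),
                      n_mean=508, role="victim"),
    )
    return ScenarioConfig(clusters=clusters, seed=seed)
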