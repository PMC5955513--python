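import numpy as np
import pandas as pd
import pytest

from hotcube.events import ProjectedPoints


def make_points(x, y, crs_tag="tm:127.0,37.55") -> ProjectedPoints:
    """Wrap raw planar coordinates as ProjectedPoints for direct use."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return ProjectedPoints(x=x, y=y, crs_tag=crs_tag,
                           index=pd.RangeIndex(len(x)))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_events_csv(tmp_path):
    """A well-formed 3-row event CSV in the canonical schema."""
    path = tmp_path / "events.csv"
    path.write_text(
        "event_id,lon,lat,timestamp,driver_age,victim_age,gender,weather\n"
        "a1,127.01,37.55,2013-03-15 13:30,70,34,M,clear\n"
        "a2,127.02,37.56,2013-06-01 09:15,40,68,F,rain\n"
        "a3,126.99,37.54,2013-11-20 18:05,65,65,F,cloudy\n")
    return path


# ---------------------------------------------------------------------------
# Independent oracles (naive implementations kept free of package internals)
# ---------------------------------------------------------------------------

def naive_gi_star(x: np.ndarray, neighbor_fn) -> np.ndarray:
    """Direct double-loop evaluation of the Gi* z formula.

    ``x`` is any-dimensional; ``neighbor_fn(flat_index) -> list of flat
    indices`` defines the binary weights (self included for Gi*).
    """
    flat = x.ravel().astype(float)
    n = flat.size
    xbar = flat.sum() / n
    s = np.sqrt((flat**2).sum() / n - xbar**2)
    z = np.zeros(n)
    for i in range(n):
        nbrs = neighbor_fn(i)
        wsum = float(len(nbrs))
        lag = sum(flat[j] for j in nbrs)
        denom = s * np.sqrt((n * wsum - wsum**2) / (n - 1))
        z[i] = 0.0 if denom == 0 else (lag - xbar * wsum) / denom
    return z.reshape(x.shape)


def grid_neighbor_fn(shape, cell_size, band, include_self=True):
    """Flat-index neighbour lists for distance-band weights on a grid."""
    nr, nc = shape

    def fn(i):
        r, c = divmod(i, nc)
        out = []
        for rr in range(nr):
            for cc in range(nc):
                d = cell_size * np.hypot(rr - r, cc - c)
                if d <= band * (1 + 1e-12):
                    if (rr, cc) == (r, c) and not include_self:
                        continue
                    out.append(rr * nc + cc)
        return out

    return fn


def st_neighbor_fn(shape, cell_size, band, time_lag):
    """Flat-index neighbours for the space-time Gi* (past-bins window)."""
    nr, nc, nt = shape

    def fn(i):
        r, rem = divmod(i, nc * nt)
        c, t = divmod(rem, nt)
        out = []
        for rr in range(nr):
            for cc in range(nc):
                if cell_size * np.hypot(rr - r, cc - c) > band * (1 + 1e-12):
                    continue
                for tt in range(max(0, t - time_lag), t + 1):
                    out.append(rr * nc * nt + cc * nt + tt)
        return out

    return fn


def naive_stkde(xs, ys, ts, ev_x, ev_y, ev_t, h_s, h_t, scale) -> np.ndarray:
    """Triple loop over voxels and events, transcribing the product
    Epanechnikov estimator one term at a time."""
    import math

    n = len(ev_x)
    out = np.zeros((len(xs), len(ys), len(ts)))
    const = scale / (n * h_s**2 * h_t)
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            for k, t in enumerate(ts):
                acc = 0.0
                for xi, yi, ti in zip(ev_x, ev_y, ev_t):
                    u = (x - xi) / h_s
                    v = (y - yi) / h_s
                    w = (t - ti) / h_t
                    if u**2 + v**2 < 1 and w**2 < 1:
                        ks = (2 / math.pi) * (1 - u**2 - v**2)
                        kt = 0.75 * (1 - w**2)
                        acc += const * ks * kt
                out[i, j, k] = acc
    return out


def brute_mann_kendall_s(series) -> int:
    a = list(series)
    return sum(np.sign(a[j] - a[i])
               for i in range(len(a)) for j in range(i + 1, len(a)))
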