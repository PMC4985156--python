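"""First-passage-time analysis and area-restricted-search detection.

First passage time (FPT) at radius r, evaluated at a point of a movement
path, is the time the animal takes to cross a circle of radius r centred
there: the interval from the last entry into the circle while approaching
to the first exit while leaving. Plotting the variance of log(FPT) against
r reveals the spatial scale of area-restricted search (ARS) as a peak:
inside a foraging patch the animal is slow and tortuous, so FPT at the
patch scale is long there and short elsewhere, maximising the spread.

The analysis runs in two nested steps — a coarse pass (r = 1–50 km,
evaluated every 1 km) for large-scale ARS and a fine pass (r = 0.1–10 km,
every 0.1 km) for small-scale events — on paths that have had low-speed
rest bouts removed and been re-sampled to a constant 0.1 km step, so that
evaluation points are equidistant in space rather than in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import LocalProjection
from .trajectory import Trip

#: coarse pass: radii 1..50 km step 1, FPT evaluated every 1 km
LARGE_SCALE_GRID = np.arange(1, 51, dtype=float)
LARGE_SCALE_EVAL_KM = 1.0
#: fine pass: radii 0.1..10 km step 0.1, FPT evaluated every 0.1 km
SMALL_SCALE_GRID = np.round(np.arange(1, 101) * 0.1, 10)
SMALL_SCALE_EVAL_KM = 0.1

REST_SPEED_KMH = 3.0
PATH_SPACING_KM = 0.1


@dataclass
class InterpolatedPath:
    """Path re-sampled at constant along-track spacing on the colony plane."""

    x: np.ndarray  # km east of colony
    y: np.ndarray  # km north of colony
    t_h: np.ndarray  # hours since trip start (monotone non-decreasing)
    spacing_km: float
    trip_id: str = ""
    t0: pd.Timestamp | None = None
    projection: LocalProjection | None = None

    def __len__(self):
        return len(self.x)


@dataclass
class FPTProfile:
    """FPT matrix over a radius grid with its variance-of-log spectrum."""

    radii: np.ndarray
    eval_indices: np.ndarray
    fpt_h: np.ndarray  # (n_eval, n_radii), NaN where undefined
    var_log_fpt: np.ndarray  # per radius, NaN where < 3 defined values
    peak_radii: np.ndarray  # interior local maxima, largest variance first


@dataclass
class ARSZone:
    trip_id: str
    r_star_km: float
    center_lon: float
    center_lat: float
    entry_time: pd.Timestamp
    max_fpt_h: float
    distance_to_colony_km: float
    scale_label: str | None = None


def preprocess_path(trip: Trip, colony_lonlat,
                    rest_speed_kmh: float = REST_SPEED_KMH,
                    spacing_km: float = PATH_SPACING_KM) -> InterpolatedPath:
    """Remove rest bouts and re-sample a trip at constant along-path spacing.

    Maximal runs of fixes slower than ``rest_speed_kmh`` (resting/preening
    on the water or on the ground) collapse to a single point carrying the
    run's first position and timestamp, so time "parked" does not masquerade
    as small-scale search. The remaining polyline is then linearly
    re-sampled every ``spacing_km`` along track, timestamps interpolated.
    """
    if len(trip.fixes) < 2:
        raise ValueError("trip too short to interpolate")
    proj = LocalProjection(*colony_lonlat)
    x, y = proj.forward(trip.fixes["lon"].to_numpy(), trip.fixes["lat"].to_numpy())
    t = ((trip.fixes["timestamp_utc"] - trip.start).dt.total_seconds() / 3600.0
         ).to_numpy()
    slow = trip.fixes["speed_kmh"].to_numpy() < rest_speed_kmh
    keep_x, keep_y, keep_t = [], [], []
    i = 0
    n = len(slow)
    while i < n:
        if slow[i]:
            j = i
            while j + 1 < n and slow[j + 1]:
                j += 1
            keep_x.append(x[i]); keep_y.append(y[i]); keep_t.append(t[i])
            i = j + 1
        else:
            keep_x.append(x[i]); keep_y.append(y[i]); keep_t.append(t[i])
            i += 1
    xk = np.asarray(keep_x); yk = np.asarray(keep_y); tk = np.asarray(keep_t)
    if len(xk) < 2:
        raise ValueError("all fixes below rest speed; no path to analyse")

    seg = np.hypot(np.diff(xk), np.diff(yk))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    # drop zero-length segments so the arc-length axis is strictly increasing
    keep = np.concatenate([[True], np.diff(s) > 1e-12])
    xk, yk, tk, s = xk[keep], yk[keep], tk[keep], s[keep]
    if s[-1] <= 0:
        raise ValueError("path has zero length after rest-bout removal")
    n_out = int(np.floor(s[-1] / spacing_km + 1e-9)) + 1
    si = np.arange(n_out) * spacing_km
    return InterpolatedPath(x=np.interp(si, s, xk), y=np.interp(si, s, yk),
                            t_h=np.interp(si, s, tk), spacing_km=spacing_km,
                            trip_id=trip.individual_id, t0=trip.start,
                            projection=proj)


def _fpt_one_side(d, t, radii):
    """First crossing time of each radius along one direction of the path.

    ``d``/``t`` start at the evaluation point. Returns crossing times
    (NaN where the path ends inside the circle), linearly interpolating the
    distance-to-centre function within the crossing segment.
    """
    out = np.full(len(radii), np.nan)
    if len(d) < 2:
        return out
    cm = np.maximum.accumulate(d)
    idx = np.searchsorted(cm, radii, side="right")
    ok = idx < len(d)
    ii = idx[ok]
    d0 = d[ii - 1]
    d1 = d[ii]
    frac = np.where(d1 > d0, (radii[ok] - d0) / np.where(d1 > d0, d1 - d0, 1.0), 1.0)
    out[ok] = t[ii - 1] + frac * (t[ii] - t[ii - 1])
    return out


def fpt_matrix(path: InterpolatedPath, radii, eval_indices) -> np.ndarray:
    """FPT (hours) at each evaluation point for each radius; NaN = undefined.

    An entry is undefined when the path starts or ends inside the circle,
    so no complete passage through it is observed.
    """
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    x, y, t = path.x, path.y, path.t_h
    out = np.full((len(eval_indices), len(radii)), np.nan)
    for row, i in enumerate(eval_indices):
        d = np.hypot(x - x[i], y - y[i])
        t_exit = _fpt_one_side(d[i:], t[i:], radii)
        t_entry = _fpt_one_side(d[i::-1], t[i::-1], radii)
        out[row] = t_exit - t_entry
    return out


def compute_fpt(path: InterpolatedPath, radius_km: float) -> np.ndarray:
    """FPT at one radius for every path point (NaN near the path ends)."""
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    return fpt_matrix(path, [radius_km], np.arange(len(path)))[:, 0]


def variance_spectrum(path: InterpolatedPath, r_grid,
                      eval_spacing_km: float) -> FPTProfile:
    """var(log FPT) across a radius grid, with candidate ARS scales.

    The variance at each radius is taken over defined FPT values only and
    reported as NaN when fewer than 3 are defined. Candidate ARS scales are
    the interior local maxima of the variance curve, returned largest
    variance first.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(np.diff(r_grid) <= 0) or np.any(r_grid <= 0):
        raise ValueError("radius grid must be positive and strictly increasing")
    step = max(int(round(eval_spacing_km / path.spacing_km)), 1)
    eval_idx = np.arange(0, len(path), step)
    mat = fpt_matrix(path, r_grid, eval_idx)
    var = np.full(len(r_grid), np.nan)
    for k in range(len(r_grid)):
        col = mat[:, k]
        col = col[np.isfinite(col) & (col > 0)]
        if len(col) >= 3:
            var[k] = np.log(col).var(ddof=1)
    peaks = _local_maxima(r_grid, _smooth3(var))
    return FPTProfile(radii=r_grid, eval_indices=eval_idx, fpt_h=mat,
                      var_log_fpt=var, peak_radii=peaks)


def _smooth3(v):
    """Centred 3-point moving average, NaN-aware, endpoints kept.

    Peak picking runs on this lightly smoothed curve: it automates what
    reading the variance plot by eye does, ignoring single-bin jitter in
    favour of the broad maxima that mark ARS scales.
    """
    out = np.array(v, dtype=float)
    for k in range(1, len(v) - 1):
        window = [w for w in (v[k - 1], v[k], v[k + 1]) if np.isfinite(w)]
        if window and np.isfinite(v[k]):
            out[k] = float(np.mean(window))
    return out


def _local_maxima(r, v, floor=1e-10):
    """Interior local maxima of v over r, ordered by descending v.

    Values at or below ``floor`` are noise around a flat (constant-FPT)
    spectrum and are never peaks.
    """
    cand = []
    for k in range(1, len(v) - 1):
        if not np.isfinite(v[k]) or v[k] <= floor:
            continue
        left = v[k - 1] if np.isfinite(v[k - 1]) else -np.inf
        right = v[k + 1] if np.isfinite(v[k + 1]) else -np.inf
        if v[k] > left and v[k] >= right:
            cand.append((v[k], r[k]))
    cand.sort(key=lambda p: -p[0])
    return np.asarray([r_ for _, r_ in cand])


def otsu_threshold(values: np.ndarray):
    """Two-class split of a 1-D sample maximising between-class variance.

    Returns ``(threshold, separation)`` where separation is the fraction of
    total variance explained by the split (0..1).
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    total_var = v.var()
    if n < 3 or total_var == 0:
        return float(np.median(v)), 0.0
    best = (-np.inf, None)
    csum = np.cumsum(v)
    tot = csum[-1]
    for k in range(1, n):  # split: v[:k] | v[k:]
        w0 = k / n
        w1 = 1.0 - w0
        mu0 = csum[k - 1] / k
        mu1 = (tot - csum[k - 1]) / (n - k)
        between = w0 * w1 * (mu0 - mu1) ** 2
        if between > best[0]:
            best = (between, 0.5 * (v[k - 1] + v[k]))
    return float(best[1]), float(best[0] / total_var)


def bimodality_coefficient(values: np.ndarray) -> float:
    """Sarle's bimodality coefficient with finite-sample correction.

    ``(g1^2 + 1) / (g2 + 3 (n-1)^2 / ((n-2)(n-3)))``; values above 5/9
    (the uniform distribution's coefficient) suggest more than one mode.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 4:
        return 0.0
    from scipy import stats as _st
    g1 = _st.skew(v, bias=False)
    g2 = _st.kurtosis(v, fisher=True, bias=False)
    return float((g1 ** 2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


def fpt_threshold(fpt_values: np.ndarray) -> float:
    """Automated stand-in for choosing an FPT threshold by eye.

    When log(FPT) looks bimodal (bimodality coefficient above 5/9, i.e.
    separate transit and search components), the threshold is the Otsu
    two-class split of log(FPT); for an effectively unimodal distribution
    it falls back to the 75th percentile.
    """
    v = np.asarray(fpt_values, dtype=float)
    v = v[np.isfinite(v) & (v > 0)]
    if len(v) == 0:
        raise ValueError("no defined FPT values")
    logv = np.log(v)
    if bimodality_coefficient(logv) > 5.0 / 9.0:
        thr, _ = otsu_threshold(logv)
    else:
        thr = np.quantile(logv, 0.75)
    return float(np.exp(thr))


def detect_ars_zones(path: InterpolatedPath, r_star_km: float,
                     colony_xy=(0.0, 0.0), threshold_h: float | None = None):
    """Delineate ARS zones as contiguous runs of FPT above a threshold.

    FPT at the chosen scale ``r_star_km`` is evaluated at every path point;
    maximal above-threshold runs become zones carrying their entry time,
    maximum residence time (max FPT within the run), the position of that
    maximum, and its great-circle distance to the colony.
    """
    fpt = compute_fpt(path, r_star_km)
    if threshold_h is None:
        threshold_h = fpt_threshold(fpt)
    above = np.isfinite(fpt) & (fpt > threshold_h)
    if not above.any():
        return []
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    zones = []
    for s, e in zip(edges[::2], edges[1::2]):
        seg = fpt[s:e]
        k = s + int(np.argmax(seg))
        t_entry = path.t_h[s]
        entry = (path.t0 + pd.Timedelta(hours=float(t_entry))
                 if path.t0 is not None else pd.Timestamp(0, tz="UTC"))
        cx, cy = float(path.x[k]), float(path.y[k])
        if path.projection is not None:
            lon, lat = path.projection.inverse(cx, cy)
        else:
            lon, lat = np.nan, np.nan
        zones.append(ARSZone(
            trip_id=path.trip_id, r_star_km=float(r_star_km),
            center_lon=float(lon), center_lat=float(lat),
            entry_time=entry, max_fpt_h=float(seg.max()),
            distance_to_colony_km=float(np.hypot(cx - colony_xy[0],
                                                 cy - colony_xy[1]))))
    return zones


def assign_scale_labels(peak_radii) -> dict:
    """Map up to three candidate scales to 1st/2nd/3rd by descending radius."""
    rs = sorted(set(float(r) for r in peak_radii), reverse=True)[:3]
    labels = ["1st", "2nd", "3rd"]
    return {r: labels[i] for i, r in enumerate(rs)}


def filter_sea_trips(metrics: pd.DataFrame,
                     min_range_km: float = 7.8) -> pd.DataFrame:
    """Restrict to trips comparable between sea and land ARS analyses.

    Mixed-destination and island trips are excluded; sea trips must reach
    at least ``min_range_km`` direct distance (the distance a bird must
    cover to reach land anyway), the bound being inclusive.
    """
    keep = metrics["destination"].isin(["sea", "inland"])
    short_sea = (metrics["destination"] == "sea") & \
        (metrics["foraging_range_km"] < min_range_km)
    return metrics[keep & ~short_sea].reset_index(drop=True)
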