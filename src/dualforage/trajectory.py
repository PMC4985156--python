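"""GPS fix ingestion, foraging-trip segmentation and trip-level statistics.

A foraging trip is a maximal excursion beyond a small buffer around the
colony, extended to the buffer-crossing fixes on either side; its metrics
are the classical central-place-foraging descriptors: duration, foraging
range (maximum great-circle distance from the nest), total distance flown
and the straightness index 2 * range / total distance, which is 1 for a
perfectly direct out-and-back flight and smaller for tortuous ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geo import haversine_km
from .landscape import LandscapeMask

log = logging.getLogger(__name__)

MARINE_CLASSES = frozenset({"sea", "tidal_flat"})

#: dwell-speed cutoff (km/h) reused from the terrestrial feeding filter
DWELL_SPEED_KMH = 10.0


@dataclass
class Trip:
    """One foraging excursion, bounded by colony-buffer crossings."""

    individual_id: str
    fixes: pd.DataFrame  # timestamp_utc, lon, lat, speed_kmh (time-ordered)
    start: pd.Timestamp
    end: pd.Timestamp
    complete: bool  # starts and ends at the colony buffer

    def __post_init__(self):
        if len(self.fixes) < 2:
            raise ValueError("a trip needs at least 2 fixes")


@dataclass
class TripMetrics:
    individual_id: str
    duration_h: float
    foraging_range_km: float
    total_distance_km: float
    straightness: float
    destination: str | None
    complete: bool


def read_fixes(path, max_speed_kmh: float = 150.0):
    """Parse a delimited fix table into per-individual, time-ordered series.

    Rows are sorted per individual; duplicate timestamps keep the first
    occurrence; fixes whose implied ground speed from the previous retained
    fix exceeds ``max_speed_kmh`` are dropped as implausible. Malformed
    rows are logged and skipped.

    Returns ``(series, report)`` where ``series`` maps individual id to a
    DataFrame and ``report`` counts dropped rows per reason.
    """
    raw = pd.read_csv(path, dtype=str, on_bad_lines="skip")
    if raw.empty:
        raise ValueError(f"no fixes in {path}")
    expected = {"id", "timestamp_utc", "lon", "lat", "speed_kmh"}
    missing = expected - set(raw.columns)
    if missing:
        raise ValueError(f"missing columns in {path}: {sorted(missing)}")
    n_in = len(raw)
    df = pd.DataFrame({
        "id": raw["id"],
        "timestamp_utc": pd.to_datetime(raw["timestamp_utc"], errors="coerce",
                                        utc=True, format="ISO8601"),
        "lon": pd.to_numeric(raw["lon"], errors="coerce"),
        "lat": pd.to_numeric(raw["lat"], errors="coerce"),
        "speed_kmh": pd.to_numeric(raw["speed_kmh"], errors="coerce"),
    })
    bad = (df[["timestamp_utc", "lon", "lat", "speed_kmh"]].isna().any(axis=1)
           | ~df["lon"].between(-180, 180) | ~df["lat"].between(-90, 90)
           | (df["speed_kmh"] < 0))
    n_malformed = int(bad.sum())
    if n_malformed:
        log.warning("%s: skipped %d malformed rows", path, n_malformed)
    df = df[~bad]

    series = {}
    report = {"rows": n_in, "malformed": n_malformed,
              "duplicate_timestamps": 0, "speed_filtered": 0}
    for ind, g in df.groupby("id", sort=True):
        g = g.sort_values("timestamp_utc", kind="mergesort")
        n0 = len(g)
        g = g.drop_duplicates("timestamp_utc", keep="first")
        report["duplicate_timestamps"] += n0 - len(g)
        keep = _speed_filter(g, max_speed_kmh)
        report["speed_filtered"] += int((~keep).sum())
        series[ind] = g[keep].drop(columns="id").reset_index(drop=True)
    if report["speed_filtered"]:
        log.info("%s: dropped %d fixes above %.0f km/h implied speed",
                 path, report["speed_filtered"], max_speed_kmh)
    return series, report


def _speed_filter(g: pd.DataFrame, max_speed_kmh: float) -> np.ndarray:
    """Greedy pass keeping fixes whose speed from the last kept fix is plausible."""
    lon = g["lon"].to_numpy()
    lat = g["lat"].to_numpy()
    t = g["timestamp_utc"].astype("int64").to_numpy() // 10 ** 9  # epoch seconds
    keep = np.ones(len(g), dtype=bool)
    last = 0
    for i in range(1, len(g)):
        dt_h = (t[i] - t[last]) / 3600.0
        if dt_h <= 0:
            keep[i] = False
            continue
        d = haversine_km(lon[last], lat[last], lon[i], lat[i])
        if d / dt_h > max_speed_kmh:
            keep[i] = False
        else:
            last = i
    return keep


def segment_trips(series: pd.DataFrame, individual_id: str, colony_lonlat,
                  buffer_km: float = 0.5, min_duration_h: float = 0.5):
    """Cut a fix series into foraging trips leaving a colony buffer.

    Maximal runs of fixes farther than ``buffer_km`` from the colony are
    extended to the bounding buffer-crossing fixes (marking the trip
    complete when both exist); runs spanning less than ``min_duration_h``
    are discarded. A series that never leaves the buffer yields no trips.
    """
    if series["timestamp_utc"].is_monotonic_increasing is False:
        raise ValueError("fix series must be time-ordered")
    d = haversine_km(colony_lonlat[0], colony_lonlat[1],
                     series["lon"].to_numpy(), series["lat"].to_numpy())
    outside = d > buffer_km
    if not outside.any():
        return []
    padded = np.concatenate([[False], outside, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    trips = []
    for s, e in zip(edges[::2], edges[1::2]):  # run = fixes s..e-1 outside
        i0 = max(s - 1, 0)
        i1 = min(e, len(series) - 1)
        sub = series.iloc[i0:i1 + 1]
        start = sub["timestamp_utc"].iloc[0]
        end = sub["timestamp_utc"].iloc[-1]
        if (end - start).total_seconds() / 3600.0 < min_duration_h:
            continue
        if len(sub) < 2:
            continue
        complete = (s - 1 >= 0) and (e <= len(series) - 1)
        trips.append(Trip(individual_id=individual_id,
                          fixes=sub.reset_index(drop=True),
                          start=start, end=end, complete=complete))
    return trips


def trip_metrics(trip: Trip, colony_lonlat, mask: LandscapeMask | None = None,
                 **classify_kwargs) -> TripMetrics:
    """Duration, foraging range, total distance and straightness of one trip."""
    if len(trip.fixes) < 2:
        raise ValueError("cannot compute metrics for a single-fix trip")
    lon = trip.fixes["lon"].to_numpy()
    lat = trip.fixes["lat"].to_numpy()
    rng_km = float(haversine_km(colony_lonlat[0], colony_lonlat[1], lon, lat).max())
    legs = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    total = float(legs.sum())
    duration = (trip.end - trip.start).total_seconds() / 3600.0
    straight = 2.0 * rng_km / total if total > 0 else np.nan
    if trip.complete:
        straight = min(straight, 1.0)
    dest = classify_destination(trip, mask, **classify_kwargs) if mask else None
    return TripMetrics(individual_id=trip.individual_id, duration_h=duration,
                       foraging_range_km=rng_km, total_distance_km=total,
                       straightness=straight, destination=dest,
                       complete=trip.complete)


def classify_destination(trip: Trip, mask: LandscapeMask,
                         dwell_speed_kmh: float = DWELL_SPEED_KMH,
                         mixed_min_frac: float = 0.10) -> str:
    """Destination class of a trip: sea, inland, mixed or island.

    Dwell fixes (device speed below ``dwell_speed_kmh``, outside the colony)
    are classified by the land/sea mask; a trip is ``sea`` when dwell is
    marine (open sea or tidal flats), ``inland`` when over the mainland,
    ``mixed`` when both sides each hold at least ``mixed_min_frac`` of the
    dwell fixes, and ``island`` when the bird only dwelt on islands. With
    no dwell fixes at all, the class of the most distant fix decides.
    """
    fx = trip.fixes
    classes = mask.classify_many(fx["lon"].to_numpy(), fx["lat"].to_numpy())
    dwell = (fx["speed_kmh"].to_numpy() < dwell_speed_kmh) & (classes != "colony")
    if not dwell.any():
        d = haversine_km(mask.colony_lonlat[0], mask.colony_lonlat[1],
                         fx["lon"].to_numpy(), fx["lat"].to_numpy())
        far = classes[int(np.argmax(d))]
        return {"mainland": "inland", "island": "island"}.get(far, "sea")
    dc = classes[dwell]
    n_marine = int(np.isin(dc, list(MARINE_CLASSES)).sum())
    n_land = int((dc == "mainland").sum())
    n_isl = int((dc == "island").sum())
    if n_marine == 0 and n_land == 0:
        return "island" if n_isl > 0 else "sea"
    n_both = n_marine + n_land
    if n_marine > 0 and n_land > 0:
        if (n_marine / n_both >= mixed_min_frac
                and n_land / n_both >= mixed_min_frac):
            return "mixed"
        return "sea" if n_marine >= n_land else "inland"
    return "sea" if n_marine > 0 else "inland"


_METRIC_COLS = ["duration_h", "foraging_range_km", "total_distance_km",
                "straightness"]


def metrics_frame(metrics) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in metrics])


def summarize_trips(metrics) -> pd.DataFrame:
    """Per-destination and overall summary: n, percentage, mean/SE/min/max.

    SE is reported as NaN for classes with a single trip.
    """
    df = metrics if isinstance(metrics, pd.DataFrame) else metrics_frame(metrics)
    if df.empty:
        raise ValueError("no trips to summarize")
    total = len(df)
    rows = []
    groups = [("all", df)] + [(k, g) for k, g in df.groupby("destination")]
    for name, g in groups:
        row = {"destination": name, "n": len(g),
               "pct": round(100.0 * len(g) / total, 1)}
        for c in _METRIC_COLS:
            v = g[c].to_numpy(dtype=float)
            row[f"{c}_mean"] = v.mean()
            row[f"{c}_se"] = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan
            row[f"{c}_min"] = v.min()
            row[f"{c}_max"] = v.max()
        rows.append(row)
    return pd.DataFrame(rows)


def diel_budget(trips, mask: LandscapeMask, utc_offset_h: float = 2.0,
                by: str = "hour") -> pd.DataFrame:
    """Mean (± SE over individuals) share of trip fixes over sea vs land.

    ``by='hour'`` bins fixes by local clock hour (UTC + fixed offset);
    ``by='weekday'`` aggregates by day of week (0 = Monday). Shares are
    computed per individual from trip fixes classified marine (open sea or
    tidal flat) vs mainland; bins with no fixes for any individual are
    excluded and flagged in the ``n_individuals`` column.
    """
    if by not in ("hour", "weekday"):
        raise ValueError("by must be 'hour' or 'weekday'")
    recs = []
    for trip in trips:
        fx = trip.fixes
        classes = mask.classify_many(fx["lon"].to_numpy(), fx["lat"].to_numpy())
        local = fx["timestamp_utc"] + pd.Timedelta(hours=utc_offset_h)
        key = local.dt.hour if by == "hour" else local.dt.weekday
        for k, cls in zip(key, classes):
            if cls in MARINE_CLASSES or cls == "mainland":
                recs.append((trip.individual_id, int(k), cls == "mainland"))
    if not recs:
        raise ValueError("no classifiable trip fixes")
    df = pd.DataFrame(recs, columns=["individual_id", "bin", "is_land"])
    per_ind = (df.groupby(["bin", "individual_id"])["is_land"]
               .mean().rename("land_share").reset_index())
    out = (per_ind.groupby("bin")["land_share"]
           .agg(land_share_mean="mean",
                land_share_se=lambda v: v.std(ddof=1) / np.sqrt(len(v))
                if len(v) > 1 else np.nan,
                n_individuals="count")
           .reset_index())
    out["sea_share_mean"] = 1.0 - out["land_share_mean"]
    return out


def variance_ratio_test(a, b):
    """Two-sided F-test comparing the variances of two samples.

    Returns ``(F, p)`` with ``F = s_a^2 / s_b^2`` on (n_a-1, n_b-1) df.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if vb == 0:
        raise ValueError("zero variance in denominator sample")
    F = va / vb
    dist = stats.f(len(a) - 1, len(b) - 1)
    p = 2.0 * min(dist.cdf(F), dist.sf(F))
    return float(F), float(min(p, 1.0))
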