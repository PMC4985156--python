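"""Seeded synthetic data with the structure of a dual-foraging seabird study.

The generator emulates GPS logger data from a colony of central-place
foragers that split their trips between the open sea (to the NNW) and
agricultural mainland (to the S): near-straight commuting legs at flight
speed, a slow, tortuous correlated-random-walk (CRW) bout inside a
foraging patch at the destination (the area-restricted-search signal the
FPT analysis is meant to recover), and low-speed dwell at the colony
between trips. Land trips are confined to a daylight window; sea trips can
start at any hour. A polygonal island / tidal-flat / mainland / sea
landscape, a habitat-parcel grid, a habitat-availability survey and
two-endmember isotope samples complete the inputs every downstream stage
assumes.

All randomness flows from one root seed, split deterministically
(``seed + individual index`` for tracks; fixed offsets for landscape and
isotopes), so identical configurations yield byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box

from .geo import LocalProjection
from .landscape import HabitatGrid, LandscapeMask

#: Habitat availability proportions of a coastal agricultural landscape
#: (counts out of 1292 surveyed segments).
DEFAULT_HABITAT_MIX = {
    "grassland": 824 / 1292,
    "corn": 248 / 1292,
    "winter_wheat": 90 / 1292,
    "barley": 61 / 1292,
    "rye": 15 / 1292,
    "potato": 12 / 1292,
    "rape": 10 / 1292,
    "oat": 8 / 1292,
    "fallow_land": 6 / 1292,
    "construction_area": 6 / 1292,
    "ploughed_soil": 5 / 1292,
    "summer_wheat": 3 / 1292,
    "pea": 2 / 1292,
    "water_body": 2 / 1292,
}

FIX_COLUMNS = ["id", "timestamp_utc", "lon", "lat", "speed_kmh"]

_EPOCH = pd.Timestamp("2010-05-17T00:00:00", tz="UTC")


@dataclass
class SimConfig:
    """Study conditions for the synthetic forager.

    Speeds and turning concentrations are assumptions (no flight-speed
    distribution is available for the study species); defaults are chosen
    to be realistic for a mid-sized gull and are documented in the methods
    note.
    """

    seed: int = 0
    n_individuals: int = 8
    n_trips_per_individual: int = 13
    fix_interval_min: float = 3.0
    p_sea: float = 0.481
    sea_bearing_deg: float = 330.0
    land_bearing_deg: float = 180.0
    commute_speed_kmh: float = 40.0
    trip_range_km: float = 30.0
    trip_range_sd_km: float = 10.0
    trip_range_min_km: float = 10.0
    trip_range_max_km: float = 75.0
    # sea trips are far more variable than inland ones (short hops to nearby
    # trawlers through long offshore excursions); land destinations are
    # bounded below by the distance to the mainland
    sea_range_sd_factor: float = 2.0
    sea_range_min_km: float = 4.0
    patch_radius_km: float = 5.0
    patch_dwell_h: float = 2.0
    patch_speed_kmh: float = 8.0
    rest_speed_kmh: float = 0.5
    colony_lonlat: tuple = (7.76, 53.78)
    daylight_window: tuple = (4.0, 22.0)  # local clock hours for land trips
    utc_offset_h: float = 2.0  # CEST
    colony_dwell_h: float = 3.0
    habitat_mix: dict = field(default_factory=lambda: dict(DEFAULT_HABITAT_MIX))
    isotope_endmembers: tuple = (-26.0, -17.0, 8.0, 15.0)  # C_land, C_sea, N_land, N_sea
    isotope_noise_sd: float = 0.5
    crw_rho_commute: float = 0.97
    crw_rho_patch: float = 0.3
    bearing_jitter_deg: float = 12.0
    speed_noise_sd_kmh: float = 0.5

    def __post_init__(self):
        if self.n_individuals <= 0 or self.n_trips_per_individual <= 0:
            raise ValueError("n_individuals and n_trips_per_individual must be positive")
        if not 0.0 <= self.p_sea <= 1.0:
            raise ValueError("p_sea must lie in [0, 1]")
        if self.fix_interval_min <= 0:
            raise ValueError("fix_interval_min must be positive")
        if self.patch_radius_km <= 0:
            raise ValueError("patch_radius_km must be positive")
        if not 0 <= self.rest_speed_kmh < 3.0:
            raise ValueError("rest_speed_kmh must lie in [0, 3)")
        if self.habitat_mix:
            total = sum(self.habitat_mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"habitat_mix proportions sum to {total}, not 1")


@dataclass
class SimTracks:
    """Simulated fixes plus the ground-truth trip schedule used to make them."""

    fixes: dict  # individual id -> DataFrame(timestamp_utc, lon, lat, speed_kmh)
    truth: pd.DataFrame  # one row per simulated trip


def _wrapped_cauchy(rng, rho, size=None):
    """Wrapped-Cauchy turning angles (radians), mean 0, concentration rho."""
    u = rng.random(size)
    return 2.0 * np.arctan(((1.0 - rho) / (1.0 + rho)) * np.tan(np.pi * (u - 0.5)))


def _crw_leg(rng, cfg, start_xy, target_xy, speed, dt_h, rho, stop_km):
    """CRW steps of fixed length drawn toward a target; stops within stop_km."""
    pts = []
    x, y = start_xy
    step = speed * dt_h
    for _ in range(100000):
        dx, dy = target_xy[0] - x, target_xy[1] - y
        dist = float(np.hypot(dx, dy))
        if dist <= max(stop_km, step):
            break
        heading = np.arctan2(dx, dy) + _wrapped_cauchy(rng, rho)
        x += step * np.sin(heading)
        y += step * np.cos(heading)
        pts.append((x, y))
    return pts


def _patch_bout(rng, cfg, start_xy, center_xy, t_steps):
    """Slow, tortuous search spanning the patch: a CRW between waypoints.

    Successive waypoints are drawn uniformly in the patch disc, so the
    realized search area matches the configured patch radius instead of
    being limited by the diffusive range of the walk.
    """
    step = cfg.patch_speed_kmh * cfg.fix_interval_min / 60.0
    x, y = start_xy

    def new_waypoint():
        r = cfg.patch_radius_km * np.sqrt(rng.random())
        a = rng.uniform(0, 2 * np.pi)
        return (center_xy[0] + r * np.sin(a), center_xy[1] + r * np.cos(a))

    wp = new_waypoint()
    pts = []
    for _ in range(t_steps):
        if np.hypot(wp[0] - x, wp[1] - y) <= step:
            wp = new_waypoint()
        heading = np.arctan2(wp[0] - x, wp[1] - y) \
            + _wrapped_cauchy(rng, cfg.crw_rho_patch)
        x += step * np.sin(heading)
        y += step * np.cos(heading)
        pts.append((x, y))
    return pts


def _local_hour(t_h, cfg):
    return (t_h + cfg.utc_offset_h) % 24.0


def simulate_tracks(config: SimConfig) -> SimTracks:
    """Generate per-individual fix series alternating colony dwell and trips.

    Returns a :class:`SimTracks` whose ``fixes`` map individual ids to
    time-ordered DataFrames (columns ``timestamp_utc, lon, lat,
    speed_kmh``) and whose ``truth`` table records each simulated trip's
    schedule, destination class and patch placement for validation.
    """
    cfg = config
    proj = LocalProjection(*cfg.colony_lonlat)
    dt_h = cfg.fix_interval_min / 60.0
    fixes = {}
    truth_rows = []
    for idx in range(cfg.n_individuals):
        rng = np.random.default_rng(cfg.seed + idx)
        ind = f"gull{idx + 1:02d}"
        rows = []  # (t_h, x, y, true_speed)
        t = rng.uniform(0.0, 4.0)

        def dwell_until(t_from, t_to):
            tt = t_from
            out = []
            while tt < t_to:
                jx, jy = rng.normal(0.0, 0.03, size=2)
                out.append((tt, jx, jy, abs(rng.normal(cfg.rest_speed_kmh, 0.2))))
                tt += dt_h
            return out, tt

        for trip_i in range(cfg.n_trips_per_individual):
            is_sea = rng.random() < cfg.p_sea
            bearing = np.radians(
                (cfg.sea_bearing_deg if is_sea else cfg.land_bearing_deg)
                + rng.normal(0.0, cfg.bearing_jitter_deg))
            sd = cfg.trip_range_sd_km * (cfg.sea_range_sd_factor if is_sea else 1.0)
            lo = cfg.sea_range_min_km if is_sea else cfg.trip_range_min_km
            dist = float(np.clip(rng.normal(cfg.trip_range_km, sd),
                                 lo, cfg.trip_range_max_km))
            dwell_h = cfg.patch_dwell_h * rng.uniform(0.7, 1.3) if cfg.patch_dwell_h > 0 else 0.0
            est_h = 1.4 * 2.0 * dist / cfg.commute_speed_kmh + dwell_h

            # pause at the colony, for land trips until the trip fits in daylight
            t_start = t + rng.uniform(0.5, cfg.colony_dwell_h)
            if not is_sea:
                w0, w1 = cfg.daylight_window
                if est_h > (w1 - w0):
                    dwell_h = max(0.2, (w1 - w0) - 1.4 * 2.0 * dist / cfg.commute_speed_kmh)
                    est_h = 1.4 * 2.0 * dist / cfg.commute_speed_kmh + dwell_h
                for _ in range(5):
                    lh = _local_hour(t_start, cfg)
                    if lh < w0:
                        t_start += w0 - lh
                    elif lh + est_h > w1:
                        t_start += (24.0 - lh) + w0
                    else:
                        break
            pre, t = dwell_until(t, t_start)
            rows.extend(pre)

            target = (dist * np.sin(bearing), dist * np.cos(bearing))
            leg_out = _crw_leg(rng, cfg, (0.0, 0.0), target,
                               cfg.commute_speed_kmh, dt_h, cfg.crw_rho_commute,
                               stop_km=0.3)
            n_patch = int(round(dwell_h / dt_h))
            patch_start = leg_out[-1] if leg_out else target
            patch = _patch_bout(rng, cfg, patch_start, target, n_patch) if n_patch > 0 else []
            back_start = patch[-1] if patch else (leg_out[-1] if leg_out else target)
            leg_back = _crw_leg(rng, cfg, back_start, (0.0, 0.0),
                                cfg.commute_speed_kmh, dt_h, cfg.crw_rho_commute,
                                stop_km=0.3)
            t_trip0 = t
            for x, y in leg_out:
                rows.append((t, x, y, cfg.commute_speed_kmh)); t += dt_h
            for x, y in patch:
                rows.append((t, x, y, cfg.patch_speed_kmh)); t += dt_h
            for x, y in leg_back:
                rows.append((t, x, y, cfg.commute_speed_kmh)); t += dt_h
            rows.append((t, rng.normal(0, 0.03), rng.normal(0, 0.03),
                         abs(rng.normal(cfg.rest_speed_kmh, 0.2))))
            t += dt_h
            truth_rows.append({"individual_id": ind, "trip_index": trip_i,
                               "destination": "sea" if is_sea else "inland",
                               "start_h": t_trip0, "end_h": t,
                               "range_km": dist,
                               "patch_x_km": target[0], "patch_y_km": target[1],
                               "patch_dwell_h": dwell_h})
        post, t = dwell_until(t, t + 1.0)
        rows.extend(post)

        arr = np.asarray([(r[0], r[1], r[2], r[3]) for r in rows], dtype=float)
        lon, lat = proj.inverse(arr[:, 1], arr[:, 2])
        speed = np.clip(arr[:, 3] + rng.normal(0.0, cfg.speed_noise_sd_kmh, len(arr)),
                        0.0, None)
        ts = _EPOCH + pd.to_timedelta(np.round(arr[:, 0] * 3600.0).astype(np.int64),
                                      unit="s")
        fixes[ind] = pd.DataFrame({"timestamp_utc": ts, "lon": lon, "lat": lat,
                                   "speed_kmh": speed})
    truth = pd.DataFrame(truth_rows)
    truth["start"] = _EPOCH + pd.to_timedelta(np.round(truth["start_h"] * 3600).astype(np.int64), unit="s")
    truth["end"] = _EPOCH + pd.to_timedelta(np.round(truth["end_h"] * 3600).astype(np.int64), unit="s")
    return SimTracks(fixes=fixes, truth=truth)


def write_fixes(tracks: dict, path) -> None:
    """Write fixes as delimited text: id,timestamp_utc,lon,lat,speed_kmh."""
    frames = []
    for ind in sorted(tracks):
        df = tracks[ind].copy()
        df.insert(0, "id", ind)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["timestamp_utc"] = out["timestamp_utc"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False, float_format="%.6f")


def simulate_landscape(config: SimConfig, grid_cell_km: float = 0.5,
                       grid_extent_km: float = 45.0):
    """Build the island / tidal-flat / mainland / sea mask and habitat grid.

    The colony sits at the origin of the local plane, on a barrier island
    (|y| <= 1.5 km); tidal flats span 1.5–9 km to the south; the mainland
    lies beyond 9 km south and carries the habitat parcels. Everything
    else is sea. Parcel labels are drawn independently from
    ``config.habitat_mix``.
    """
    if not config.habitat_mix:
        raise ValueError("habitat_mix must be non-empty")
    total = sum(config.habitat_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("habitat_mix proportions must sum to 1")
    proj = LocalProjection(*config.colony_lonlat)

    def ll_box(x0, y0, x1, y1):
        xs = np.linspace(x0, x1, 16)
        ys = np.linspace(y0, y1, 16)
        ring = ([(x, y0) for x in xs] + [(x1, y) for y in ys]
                + [(x, y1) for x in xs[::-1]] + [(x0, y) for y in ys[::-1]])
        pts = [proj.inverse(x, y) for x, y in ring]
        from shapely.geometry import Polygon
        return Polygon([(float(a), float(b)) for a, b in pts])

    island = ll_box(-8.0, -1.5, 8.0, 1.5)
    tidal = ll_box(-60.0, -9.0, 60.0, -1.5)
    mainland = ll_box(-90.0, -120.0, 90.0, -9.0)
    sea = box(config.colony_lonlat[0] - 3.0, config.colony_lonlat[1] - 2.0,
              config.colony_lonlat[0] + 3.0, config.colony_lonlat[1] + 2.0)
    sea = sea.difference(island).difference(tidal).difference(mainland)
    mask = LandscapeMask(polygons={"island": island, "tidal_flat": tidal,
                                   "mainland": mainland, "sea": sea},
                         colony_lonlat=tuple(config.colony_lonlat))

    rng = np.random.default_rng(config.seed + 100003)
    labels = sorted(config.habitat_mix)
    probs = np.array([config.habitat_mix[k] for k in labels])
    half = grid_extent_km
    i0, i1 = int(np.floor(-half / grid_cell_km)), int(np.ceil(half / grid_cell_km))
    j0, j1 = int(np.floor(-120.0 / grid_cell_km)), int(np.floor(-9.0 / grid_cell_km))
    cells = {}
    for j in range(j0, j1):
        draws = rng.choice(len(labels), size=i1 - i0, p=probs)
        for k, i in enumerate(range(i0, i1)):
            cells[(i, j)] = labels[draws[k]]
    grid = HabitatGrid(cells=cells, cell_km=grid_cell_km,
                       colony_lonlat=tuple(config.colony_lonlat))
    return mask, grid


def simulate_survey(grid: HabitatGrid, n_segments: int, seed: int) -> pd.DataFrame:
    """Draw a habitat-availability survey: one row per surveyed segment."""
    rng = np.random.default_rng(seed + 200003)
    keys = sorted(grid.cells)
    picks = rng.choice(len(keys), size=n_segments, replace=True)
    return pd.DataFrame({
        "segment_id": [f"seg{k:05d}" for k in range(n_segments)],
        "habitat": [grid.cells[keys[p]] for p in picks],
    })


def simulate_isotopes(p_sea_per_individual, config: SimConfig) -> pd.DataFrame:
    """Two-endmember mixing samples: delta = land + p_sea * (sea - land) + noise.

    Emits one plasma and one red-blood-cell sample per individual for both
    isotopes, with tissue-typical C:N mass ratios. ``p_sea_per_individual``
    maps individual id -> proportion of foraging at sea (or is a sequence,
    in which case ids are generated).
    """
    c_land, c_sea, n_land, n_sea = config.isotope_endmembers
    if c_land == c_sea and n_land == n_sea:
        warnings.warn("isotope endmembers identical for both isotopes; "
                      "regression on p_sea is unidentifiable")
    if isinstance(p_sea_per_individual, dict):
        items = sorted(p_sea_per_individual.items())
    else:
        items = [(f"gull{i + 1:02d}", p) for i, p in enumerate(p_sea_per_individual)]
    for _, p in items:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p_sea must lie in [0, 1], got {p}")
    rng = np.random.default_rng(config.seed + 300007)
    rows = []
    for ind, p in items:
        for tissue, cn_lo, cn_hi in (("plasma", 3.8, 4.8),
                                     ("red_blood_cells", 3.2, 3.6)):
            d13c = c_land + p * (c_sea - c_land) + rng.normal(0.0, config.isotope_noise_sd)
            d15n = n_land + p * (n_sea - n_land) + rng.normal(0.0, config.isotope_noise_sd)
            rows.append({"individual_id": ind, "tissue": tissue,
                         "d13C": d13c, "d15N": d15n,
                         "c_to_n": rng.uniform(cn_lo, cn_hi),
                         "p_sea_true": p})
    return pd.DataFrame(rows)
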