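"""Terrestrial feeding-spot detection and availability-vs-use selection tests.

Feeding spots are 500 m grid cells where a bird spent at least 30 min at
ground speed, capped per individual to limit the weight of birds that
foraged inland a lot. Habitat use at those spots is compared against a
habitat-availability survey with proportional-use ratios (>1 preference,
<1 avoidance) and goodness-of-fit chi-square statistics whose p-values are
simulated by Monte-Carlo draws from the availability distribution.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geo import LocalProjection
from .landscape import HabitatGrid, LandscapeMask
from .trajectory import Trip, classify_destination

FEED_SPEED_KMH = 10.0
MIN_DWELL_MIN = 30.0
CELL_KM = 0.5
CAP_PER_INDIVIDUAL = 15
MIN_TESTABLE_AVAILABILITY = 4  # tests only for availability > 4

#: habitats counted as bare / little vegetation in the grouped comparison
NO_LITTLE_VEGETATION = frozenset({
    "corn", "potato", "summer_wheat", "ploughed_soil", "construction_area",
    "water_body", "waste_disposal",
})


def detect_feeding_spots(trips, mask: LandscapeMask, grid: HabitatGrid,
                         seed: int,
                         destinations=None,
                         max_speed_kmh: float = FEED_SPEED_KMH,
                         min_dwell_min: float = MIN_DWELL_MIN,
                         cell_km: float = CELL_KM,
                         cap_per_individual: int = CAP_PER_INDIVIDUAL,
                         contiguous: bool = False) -> pd.DataFrame:
    """Find terrestrial feeding spots from inland/mixed trips.

    Mainland fixes at speed <= ``max_speed_kmh`` are binned into
    ``cell_km`` cells anchored at the colony's projected origin; a cell
    where one trip's fixes span at least ``min_dwell_min`` (first-to-last
    by default; maximal contiguous run when ``contiguous``) and hold >= 2
    fixes becomes a spot. Individuals with more than
    ``cap_per_individual`` spots have whole trips drawn at random (seeded)
    until the cap is reached. The most-dwelled spot of each trip carries
    ``primary=True``; downstream selection tests use the primary spots.

    Returns a DataFrame (possibly empty) with one row per spot.
    """
    proj = LocalProjection(*mask.colony_lonlat)
    records = []
    for trip_no, trip in enumerate(trips):
        dest = (destinations[trip_no] if destinations is not None
                else classify_destination(trip, mask))
        if dest not in ("inland", "mixed"):
            continue
        fx = trip.fixes
        classes = mask.classify_many(fx["lon"].to_numpy(), fx["lat"].to_numpy())
        sel = (fx["speed_kmh"].to_numpy() <= max_speed_kmh) & (classes == "mainland")
        if not sel.any():
            continue
        sub = fx[sel]
        x, y = proj.forward(sub["lon"].to_numpy(), sub["lat"].to_numpy())
        ci = np.floor(x / cell_km).astype(int)
        cj = np.floor(y / cell_km).astype(int)
        t = sub["timestamp_utc"].reset_index(drop=True)
        cells = pd.DataFrame({"i": ci, "j": cj, "t": t.to_numpy()})
        for (i, j), g in cells.groupby(["i", "j"]):
            if len(g) < 2:
                continue
            if contiguous:
                dwell = _max_contiguous_span_min(cells, i, j)
            else:
                dwell = (g["t"].max() - g["t"].min()) / np.timedelta64(60, "s")
            if dwell < min_dwell_min:
                continue
            clon, clat = proj.inverse((i + 0.5) * cell_km, (j + 0.5) * cell_km)
            records.append({
                "individual_id": trip.individual_id, "trip_no": trip_no,
                "cell_i": int(i), "cell_j": int(j),
                "center_lon": float(clon), "center_lat": float(clat),
                "dwell_min": float(dwell), "n_fixes": int(len(g)),
                "habitat": grid.habitat_at(float(clon), float(clat)),
            })
    spots = pd.DataFrame(records)
    if spots.empty:
        return spots
    spots = _cap_spots(spots, cap_per_individual, seed)
    spots["primary"] = False
    idx = spots.groupby(["individual_id", "trip_no"])["dwell_min"].idxmax()
    spots.loc[idx, "primary"] = True
    return spots.reset_index(drop=True)


def _max_contiguous_span_min(cells: pd.DataFrame, i: int, j: int) -> float:
    inside = ((cells["i"] == i) & (cells["j"] == j)).to_numpy()
    t = cells["t"].to_numpy()
    best = 0.0
    k = 0
    while k < len(inside):
        if inside[k]:
            m = k
            while m + 1 < len(inside) and inside[m + 1]:
                m += 1
            span = (t[m] - t[k]) / np.timedelta64(60, "s")
            best = max(best, float(span))
            k = m + 1
        else:
            k += 1
    return best


def _cap_spots(spots: pd.DataFrame, cap: int, seed: int) -> pd.DataFrame:
    out = []
    rng = np.random.default_rng(seed)
    for ind in sorted(spots["individual_id"].unique()):
        g = spots[spots["individual_id"] == ind]
        if len(g) <= cap:
            out.append(g)
            continue
        trip_ids = sorted(g["trip_no"].unique())
        order = rng.permutation(len(trip_ids))
        chosen = []
        for k in order:
            chosen.append(g[g["trip_no"] == trip_ids[k]])
            if sum(len(c) for c in chosen) >= cap:
                break
        picked = pd.concat(chosen).iloc[:cap]
        out.append(picked)
    return pd.concat(out)


def habitat_table(survey: pd.DataFrame, spots: pd.DataFrame) -> pd.DataFrame:
    """Availability (survey segments) vs use (primary feeding spots) counts."""
    avail = survey["habitat"].value_counts()
    use_spots = spots[spots["primary"]] if "primary" in spots else spots
    use = use_spots["habitat"].value_counts()
    habitats = sorted(set(avail.index) | set(use.index))
    return pd.DataFrame({
        "habitat": habitats,
        "availability": [int(avail.get(h, 0)) for h in habitats],
        "use": [int(use.get(h, 0)) for h in habitats],
    })


def proportional_use(table: pd.DataFrame) -> pd.Series:
    """Use share over availability share per habitat (NaN when unavailable)."""
    at = table["availability"].sum()
    ut = table["use"].sum()
    if at <= 0 or ut <= 0:
        raise ValueError("availability and use totals must be positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (table["use"] / ut) / (table["availability"] / at)
    ratio[table["availability"] == 0] = np.nan
    return pd.Series(ratio.to_numpy(), index=table["habitat"].to_numpy(),
                     name="proportional_use")


def gof_chisq_mc(observed, expected_proportions, n_sim: int = 10000,
                 seed: int = 0):
    """Goodness-of-fit chi-square with a Monte-Carlo simulated p-value.

    ``chi2 = sum((obs_i - n p_i)^2 / (n p_i))``; the p-value is the add-one
    estimator ``(1 + #{chi2_sim >= chi2_obs}) / (n_sim + 1)`` over
    multinomial(n, p) draws, so it is never exactly zero.
    """
    obs = np.asarray(observed, dtype=float)
    p = np.asarray(expected_proportions, dtype=float)
    if np.any(obs < 0):
        raise ValueError("observed counts must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("expected proportions must sum to 1")
    n = obs.sum()
    exp = n * p
    if np.any(exp == 0):
        raise ValueError("zero expected count; exclude the category upstream")
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(int(n), p, size=n_sim)
    chi2_sim = ((sims - exp) ** 2 / exp).sum(axis=1)
    p_val = (1.0 + np.count_nonzero(chi2_sim >= chi2 - 1e-12)) / (n_sim + 1.0)
    return chi2, float(p_val)


@dataclass
class SelectionResult:
    table: pd.DataFrame  # per habitat: counts, ratio, chi2, p (NaN = untested)
    grouped: pd.DataFrame  # open vs ground-covering comparison
    overall_chi2: float
    overall_p: float


def selection_tests(table: pd.DataFrame, n_sim: int = 10000,
                    seed: int = 0) -> SelectionResult:
    """Proportional-use ratios and per-habitat / grouped chi-square tests.

    Per-habitat tests use the two-cell (habitat vs rest) goodness-of-fit
    form and are skipped for habitats with availability <= 4 or with zero
    availability (ratio undefined). The grouped test compares open-ground
    habitats against ground-covering vegetation. Sub-seeds derive
    deterministically from ``seed`` and the habitat name.
    """
    tab = table.copy().reset_index(drop=True)
    avail_tot = int(tab["availability"].sum())
    tab["proportional_use"] = proportional_use(tab).to_numpy()
    chis, ps = [], []
    for _, row in tab.iterrows():
        a, u = int(row["availability"]), int(row["use"])
        if a <= MIN_TESTABLE_AVAILABILITY:
            chis.append(np.nan)
            ps.append(np.nan)
            continue
        sub_seed = (seed + zlib.crc32(str(row["habitat"]).encode())) % (2 ** 31)
        c, p = gof_chisq_mc([u, tab["use"].sum() - u],
                            [a / avail_tot, 1.0 - a / avail_tot],
                            n_sim=n_sim, seed=sub_seed)
        chis.append(c)
        ps.append(p)
    tab["chi2"] = chis
    tab["p"] = ps

    open_mask = tab["habitat"].isin(NO_LITTLE_VEGETATION)
    grouped = pd.DataFrame({
        "habitat": ["no_little_vegetation", "ground_covering"],
        "availability": [int(tab.loc[open_mask, "availability"].sum()),
                         int(tab.loc[~open_mask, "availability"].sum())],
        "use": [int(tab.loc[open_mask, "use"].sum()),
                int(tab.loc[~open_mask, "use"].sum())],
    })
    grouped["proportional_use"] = proportional_use(grouped).to_numpy()
    g_chi2, g_p = gof_chisq_mc(
        grouped["use"].to_numpy(),
        grouped["availability"].to_numpy() / avail_tot,
        n_sim=n_sim, seed=seed)
    return SelectionResult(table=tab, grouped=grouped,
                           overall_chi2=g_chi2, overall_p=g_p)


def diet_frequency(pellet_items: pd.DataFrame, n_pellets: int | None = None
                   ) -> pd.Series:
    """Frequency of occurrence (%) of each prey item across pellets.

    ``pellet_items`` is a long incidence table with columns ``pellet_id``
    and ``item``. Items co-occur, so percentages may sum above 100.
    """
    if pellet_items.empty:
        raise ValueError("no pellets")
    if n_pellets is None:
        n_pellets = pellet_items["pellet_id"].nunique()
    counts = pellet_items.drop_duplicates(["pellet_id", "item"])["item"].value_counts()
    return (100.0 * counts / n_pellets).rename("fo_percent")
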