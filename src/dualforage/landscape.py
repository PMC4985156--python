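"""Land/sea classification mask and terrestrial habitat grid.

The study seascape is a barrier-island system: the breeding colony sits on
an island, a band of tidal flats separates it from the mainland to the
south, and open sea lies to the north. The mask classifies any lon/lat
point into ``{sea, tidal_flat, mainland, island}`` (plus ``colony`` inside
a small radius around the nest site); the habitat grid labels mainland
parcels with a crop/land-use type for availability-vs-use analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, mapping, shape
from shapely.prepared import prep

from .geo import LocalProjection

MASK_CLASSES = ("island", "tidal_flat", "mainland", "sea")


@dataclass
class LandscapeMask:
    """Total point classifier built from class-labelled polygons.

    Polygons are checked in the order island, tidal_flat, mainland; any
    point in none of them is sea, so every point classifies. Points within
    ``colony_radius_km`` of the colony classify as ``colony``.
    """

    polygons: dict  # class label -> shapely geometry (lon/lat degrees)
    colony_lonlat: tuple
    colony_radius_km: float = 0.2
    _prepared: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self._prepared = {k: prep(g) for k, g in self.polygons.items()}
        self._proj = LocalProjection(*self.colony_lonlat)

    def classify(self, lon: float, lat: float) -> str:
        x, y = self._proj.forward(lon, lat)
        if float(np.hypot(x, y)) <= self.colony_radius_km:
            return "colony"
        p = Point(float(lon), float(lat))
        for cls in ("island", "tidal_flat", "mainland"):
            g = self._prepared.get(cls)
            if g is not None and g.intersects(p):
                return cls
        return "sea"

    def classify_many(self, lons, lats) -> np.ndarray:
        return np.array([self.classify(lo, la) for lo, la in zip(lons, lats)],
                        dtype=object)

    def to_geojson(self, path) -> None:
        feats = [{"type": "Feature", "properties": {"class": cls},
                  "geometry": mapping(geom)}
                 for cls, geom in self.polygons.items()]
        doc = {"type": "FeatureCollection",
               "properties": {"colony_lonlat": list(self.colony_lonlat),
                              "colony_radius_km": self.colony_radius_km},
               "features": feats}
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_geojson(cls, path) -> "LandscapeMask":
        with open(path) as fh:
            doc = json.load(fh)
        polys = {f["properties"]["class"]: shape(f["geometry"])
                 for f in doc["features"]}
        props = doc.get("properties", {})
        return cls(polygons=polys,
                   colony_lonlat=tuple(props["colony_lonlat"]),
                   colony_radius_km=props.get("colony_radius_km", 0.2))


@dataclass
class HabitatGrid:
    """Square parcels on the colony-centred plane with habitat labels.

    ``cells`` maps (i, j) integer cell indices (cell size ``cell_km``,
    origin at the colony's projected coordinates) to a habitat label.
    """

    cells: dict  # (i, j) -> habitat label
    cell_km: float
    colony_lonlat: tuple

    def __post_init__(self):
        self._proj = LocalProjection(*self.colony_lonlat)

    def cell_index(self, lon: float, lat: float):
        x, y = self._proj.forward(lon, lat)
        return int(np.floor(x / self.cell_km)), int(np.floor(y / self.cell_km))

    def habitat_at(self, lon: float, lat: float):
        return self.cells.get(self.cell_index(lon, lat))

    def cell_center(self, ij):
        i, j = ij
        lon, lat = self._proj.inverse((i + 0.5) * self.cell_km,
                                      (j + 0.5) * self.cell_km)
        return float(lon), float(lat)

    def label_counts(self):
        labels, counts = np.unique(list(self.cells.values()), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def to_geojson(self, path) -> None:
        feats = []
        for (i, j), hab in self.cells.items():
            xs = [i * self.cell_km, (i + 1) * self.cell_km]
            ys = [j * self.cell_km, (j + 1) * self.cell_km]
            ring = [self._proj.inverse(x, y)
                    for x, y in [(xs[0], ys[0]), (xs[1], ys[0]),
                                 (xs[1], ys[1]), (xs[0], ys[1]),
                                 (xs[0], ys[0])]]
            feats.append({"type": "Feature",
                          "properties": {"habitat": hab, "i": i, "j": j},
                          "geometry": {"type": "Polygon",
                                       "coordinates": [[[float(a), float(b)]
                                                        for a, b in ring]]}})
        doc = {"type": "FeatureCollection",
               "properties": {"cell_km": self.cell_km,
                              "colony_lonlat": list(self.colony_lonlat)},
               "features": feats}
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_geojson(cls, path) -> "HabitatGrid":
        with open(path) as fh:
            doc = json.load(fh)
        props = doc["properties"]
        cells = {(f["properties"]["i"], f["properties"]["j"]):
                 f["properties"]["habitat"] for f in doc["features"]}
        return cls(cells=cells, cell_km=props["cell_km"],
                   colony_lonlat=tuple(props["colony_lonlat"]))
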