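"""Offline community-resource catalog and nearest-resource queries.

Replaces a live business-directory API with a file-based catalog (GeoJSON
FeatureCollection or CSV) of geolocated resources in nine categories —
weight-management programs, parks/playgrounds, fitness centers, recreation
centers, grocery stores, farmers markets, CSAs, food pantries and community
gardens. Queries are straight-line (great-circle) distance from the
patient's home; routing and travel time are out of scope.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GeoPoint",
    "Resource",
    "ResourceHit",
    "ResourceCatalog",
    "CATEGORIES",
    "CATEGORY_COLORS",
    "haversine_km",
    "find_nearby",
    "load_catalog",
]

EARTH_RADIUS_KM = 6371.0

CATEGORIES = (
    "weight_management_program",
    "park_playground",
    "fitness_sports_center",
    "community_recreation_center",
    "grocery_store",
    "farmers_market",
    "csa",
    "food_pantry",
    "community_garden",
)

# Display color per category (activity resources in greens/blues, food
# resources in warm tones) so map pins are distinguishable at a glance.
CATEGORY_COLORS = {
    "weight_management_program": "purple",
    "park_playground": "green",
    "fitness_sports_center": "blue",
    "community_recreation_center": "teal",
    "grocery_store": "orange",
    "farmers_market": "olive",
    "csa": "brown",
    "food_pantry": "red",
    "community_garden": "lime",
}


@dataclass(frozen=True)
class GeoPoint:
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range [-90, 90]: {self.lat}")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude out of range [-180, 180]: {self.lon}")


@dataclass(frozen=True)
class Resource:
    name: str
    category: str
    location: GeoPoint
    address: str = ""
    hours: str = ""
    amenities: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("resource requires a name")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; valid: {list(CATEGORIES)}"
            )
        object.__setattr__(self, "amenities", tuple(self.amenities))

    @property
    def color(self) -> str:
        return CATEGORY_COLORS[self.category]


@dataclass(frozen=True)
class ResourceHit:
    resource: Resource
    distance_km: float


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in km on a sphere of radius 6371.0 km."""
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dphi = phi2 - phi1
    dlmb = math.radians(b.lon - a.lon)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


@dataclass
class ResourceCatalog:
    resources: list[Resource] = field(default_factory=list)
    rejected: list[dict] = field(default_factory=list)  # per-record diagnostics

    @property
    def n_loaded(self) -> int:
        return len(self.resources)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _build_resource(props: dict, lat: float, lon: float) -> Resource:
    return Resource(
        name=props.get("name", ""),
        category=props.get("category", ""),
        location=GeoPoint(float(lat), float(lon)),
        address=props.get("address", "") or "",
        hours=props.get("hours", "") or "",
        amenities=tuple(
            props["amenities"]
            if isinstance(props.get("amenities"), (list, tuple))
            else [s for s in str(props.get("amenities", "")).split(";") if s]
        ),
    )


def load_catalog(path: str | Path) -> ResourceCatalog:
    """Load and validate a catalog from GeoJSON or CSV.

    Invalid records (bad geometry, unknown category, missing name) are
    rejected individually with a diagnostic; valid records still load.
    """
    path = Path(path)
    catalog = ResourceCatalog()
    if path.suffix.lower() in {".json", ".geojson"}:
        with open(path) as fh:
            doc = json.load(fh)
        features = doc.get("features", [])
        for i, feat in enumerate(features):
            try:
                geom = feat.get("geometry") or {}
                if geom.get("type") != "Point":
                    raise ValueError(f"geometry type must be Point, got {geom.get('type')!r}")
                lon, lat = geom["coordinates"][:2]
                catalog.resources.append(_build_resource(feat.get("properties") or {}, lat, lon))
            except (ValueError, KeyError, TypeError, IndexError) as exc:
                catalog.rejected.append({"record": i, "reason": str(exc)})
    else:
        with open(path, newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                try:
                    catalog.resources.append(
                        _build_resource(row, float(row["lat"]), float(row["lon"]))
                    )
                except (ValueError, KeyError, TypeError) as exc:
                    catalog.rejected.append({"record": i, "reason": str(exc)})
    return catalog


def find_nearby(
    catalog: ResourceCatalog,
    home: GeoPoint,
    categories: Iterable[str] | None = None,
    radius_km: float = 8.0,
    k: int = 10,
) -> list[ResourceHit]:
    """Nearest in-category resources within ``radius_km`` of home, closest first.

    Defaults: 8 km radius (about 5 miles), up to 10 hits. Ties are broken by
    resource name, then catalog order.
    """
    if categories is not None:
        categories = set(categories)
        unknown = categories - set(CATEGORIES)
        if unknown:
            raise ValueError(
                f"unknown categories {sorted(unknown)}; valid: {list(CATEGORIES)}"
            )
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = []
    for order, res in enumerate(catalog.resources):
        if categories is not None and res.category not in categories:
            continue
        d = haversine_km(home, res.location)
        if d <= radius_km:
            hits.append((d, res.name, order, res))
    hits.sort(key=lambda t: t[:3])
    return [ResourceHit(resource=res, distance_km=round(d, 2)) for d, _, _, res in hits[:k]]
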