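import json

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")

from cvhrx import (
    Factor,
    GeoPoint,
    RiskFactorValue,
    default_cutpoints,
    default_lms_table,
)

IDEAL_VALUES = {
    Factor.bmi_percentile: 50,
    Factor.blood_pressure: (105, 65),
    Factor.cholesterol: 150,
    Factor.glucose: 90,
    Factor.smoking: "never",
    Factor.physical_activity: 450,
    Factor.diet: 5,
}

INTERMEDIATE_VALUES = {
    Factor.bmi_percentile: 90,
    Factor.blood_pressure: (125, 70),
    Factor.cholesterol: 180,
    Factor.glucose: 110,
    Factor.smoking: "former",
    Factor.physical_activity: 100,
    Factor.diet: 3,
}

POOR_VALUES = {
    Factor.bmi_percentile: 97,
    Factor.blood_pressure: (150, 95),
    Factor.cholesterol: 220,
    Factor.glucose: 130,
    Factor.smoking: "current",
    Factor.physical_activity: 0,
    Factor.diet: 1,
}

VALUES_BY_CATEGORY = {
    "ideal": IDEAL_VALUES,
    "intermediate": INTERMEDIATE_VALUES,
    "poor": POOR_VALUES,
}


def profile_with(categories: dict) -> list[RiskFactorValue]:
    """Build a profile hitting the requested category per factor."""
    return [
        RiskFactorValue(f, value=VALUES_BY_CATEGORY[cat][f])
        for f, cat in categories.items()
    ]


@pytest.fixture(scope="session")
def lms_table():
    return default_lms_table()


@pytest.fixture(scope="session")
def cutpoints():
    return default_cutpoints()


@pytest.fixture
def all_ideal_profile():
    return profile_with({f: "ideal" for f in Factor})


@pytest.fixture
def all_poor_profile():
    return profile_with({f: "poor" for f in Factor})


CATALOG_RECORDS = [
    {"name": "Forest Park", "category": "park_playground", "lat": 38.6383, "lon": -90.2847,
     "address": "1 Park Dr", "hours": "6-22", "amenities": ["trail", "playground"]},
    {"name": "City Rec Center", "category": "community_recreation_center", "lat": 38.6270,
     "lon": -90.1994, "address": "2 Main St", "hours": "8-20", "amenities": ["pool"]},
    {"name": "Soulard Market", "category": "farmers_market", "lat": 38.6103, "lon": -90.1972,
     "address": "3 Market Ln", "hours": "Sat 7-13", "amenities": []},
    {"name": "Schnucks", "category": "grocery_store", "lat": 38.6450, "lon": -90.2620,
     "address": "4 Grocer Rd", "hours": "7-22", "amenities": ["pharmacy"]},
    {"name": "Teen Fit Clinic", "category": "weight_management_program", "lat": 38.6353,
     "lon": -90.2330, "address": "5 Clinic Way", "hours": "9-17", "amenities": []},
]


@pytest.fixture
def catalog_geojson(tmp_path):
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [r["lon"], r["lat"]]},
                "properties": {k: v for k, v in r.items() if k not in ("lat", "lon")},
            }
            for r in CATALOG_RECORDS
        ],
    }
    path = tmp_path / "catalog.geojson"
    path.write_text(json.dumps(doc))
    return path


@pytest.fixture
def home_point():
    return GeoPoint(38.6300, -90.2400)
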