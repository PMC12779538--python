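"""Reference layer: cities, economic regions, seasons and travel legs.

Maps each home city/town to a BC economic region, and to the legs of its two
in-person travel variants:

* drive — home→hospital by road, plus one of the three major ferry routes for
  Vancouver Island cities (short ferries such as the Sunshine Coast crossing
  are folded into the road distance);
* fly — home→nearest airport and YVR→hospital road legs plus the per-person
  round-trip flight footprint for that airport.

Out-of-province cities resolve their flight footprint through a configurable
airport-split table (equal shares across a province's major airports); the
packaged Alberta split is synthetic.

The packaged city fixture is a plausible synthetic stand-in: real routed road
distances are not public. Distances are data, never computed here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import pandas as pd

from .emissions import TripLegs
from .errors import ConfigurationError, InvalidInputError, ValidationError

REGIONS = frozenset(
    {
        "Mainland/Southwest",
        "Vancouver Island/Coast",
        "Thompson-Okanagan",
        "Kootenay",
        "Cariboo",
        "North Coast",
        "Nechako",
        "Northeast",
        "Out of Province",
        "Unknown",
    }
)

FERRY_ROUTES = ("Route1", "Route2", "Route3")

UNIDENTIFIED = "unidentified"


class Season(str, enum.Enum):
    """April-start fiscal half-years: Q1–Q2 are summer, Q3–Q4 winter."""

    SUMMER = "summer"  # April–September
    WINTER = "winter"  # October–March


_QUARTER_SEASON = {
    "Q1": Season.SUMMER,
    "Q2": Season.SUMMER,
    "Q3": Season.WINTER,
    "Q4": Season.WINTER,
}

QUARTERS = ("Q1", "Q2", "Q3", "Q4")


def season_for_quarter(quarter: str) -> Season:
    """Map a fiscal quarter label (Q1..Q4, fiscal year starting April 1) to a season."""
    try:
        return _QUARTER_SEASON[quarter]
    except KeyError:
        raise InvalidInputError(f"unknown fiscal quarter {quarter!r}") from None


@dataclass(frozen=True)
class CityProfile:
    """Everything needed to cost one in-person visit from a city."""

    city: str
    region: str
    long_haul: bool = False
    visit_weight: float = 1.0
    drive_km_to_hospital: float = 0.0
    ferry_route: Optional[str] = None
    drive_km_home_to_terminal: float = 0.0
    drive_km_terminal_to_hospital: float = 0.0
    ferry_route_km: float = 0.0
    airport_code: Optional[str] = None
    drive_km_home_to_airport: float = 0.0
    drive_km_airport_to_hospital: float = 0.0
    flight_roundtrip_tco2e_per_person: float = 0.0

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValidationError(f"{self.city}: unknown region {self.region!r}")
        for name in (
            "visit_weight",
            "drive_km_to_hospital",
            "drive_km_home_to_terminal",
            "drive_km_terminal_to_hospital",
            "ferry_route_km",
            "drive_km_home_to_airport",
            "drive_km_airport_to_hospital",
            "flight_roundtrip_tco2e_per_person",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.city}: {name} must be non-negative")
        if self.ferry_route is not None:
            if self.ferry_route not in FERRY_ROUTES:
                raise ValidationError(
                    f"{self.city}: unknown ferry route {self.ferry_route!r}"
                )
            if self.ferry_route_km <= 0:
                raise ValidationError(f"{self.city}: ferry route without a distance")
        if self.airport_code is not None and self.flight_roundtrip_tco2e_per_person <= 0:
            raise ValidationError(
                f"{self.city}: airport {self.airport_code} without a flight footprint"
            )


def legs_for_mode(p: CityProfile, mode: str) -> TripLegs:
    """Compose the trip legs of one mode variant for a city.

    drive: the road distance to the hospital, split around the ferry route for
    island cities. fly: road legs to the home airport and from YVR, plus the
    per-person flight footprint.
    """
    if mode == "drive":
        if p.ferry_route is not None:
            return TripLegs(
                drive_km_total=p.drive_km_home_to_terminal
                + p.drive_km_terminal_to_hospital,
                ferry_route_km=p.ferry_route_km,
            )
        return TripLegs(drive_km_total=p.drive_km_to_hospital)
    if mode == "fly":
        if p.airport_code is None:
            raise ConfigurationError(f"{p.city}: flying requested but no airport")
        return TripLegs(
            drive_km_total=p.drive_km_home_to_airport + p.drive_km_airport_to_hospital,
            flight_roundtrip_tco2e_per_person=p.flight_roundtrip_tco2e_per_person,
        )
    raise InvalidInputError(f"unknown travel mode {mode!r}")


def _data_path(name: str):
    return resources.files("visitcarbon.data") / name


def load_airports(path=None) -> pd.DataFrame:
    """Per-person round-trip flight CO2e (t) for each BC airport to YVR."""
    df = pd.read_csv(path if path is not None else _data_path("airports.csv"))
    if (df["roundtrip_tco2e"] <= 0).any():
        raise ValidationError("airport flight footprints must be positive")
    return df


def load_oop_airport_splits(path=None) -> pd.DataFrame:
    """Out-of-province airport-split table (synthetic packaged default)."""
    df = pd.read_csv(path if path is not None else _data_path("oop_airports.csv"))
    for code, grp in df.groupby("split_code"):
        if abs(grp["share"].sum() - 1.0) > 1e-9:
            raise ValidationError(f"airport split {code!r}: shares must sum to 1")
    return df


def load_ferry_routes(path=None) -> pd.DataFrame:
    return pd.read_csv(path if path is not None else _data_path("ferry_routes.csv"))


def load_populations(path=None) -> dict[str, int]:
    """Regional populations for per-capita normalisation (synthetic default)."""
    df = pd.read_csv(path if path is not None else _data_path("populations.csv"))
    if (df["population"] <= 0).any():
        raise ValidationError("populations must be positive")
    return dict(zip(df["region"], df["population"].astype(int)))


def load_city_profiles(
    path=None,
    airports: Optional[pd.DataFrame] = None,
    ferry_routes: Optional[pd.DataFrame] = None,
    oop_splits: Optional[pd.DataFrame] = None,
) -> dict[str, CityProfile]:
    """Read and validate a city-profile CSV into a city→profile mapping.

    Airport codes resolve against the airport table, or against the
    out-of-province split table (weighted-mean flight footprint). Duplicate
    cities, unknown regions/airports and negative distances are rejected with
    the offending row.
    """
    df = pd.read_csv(path if path is not None else _data_path("city_profiles.csv"))
    airports = airports if airports is not None else load_airports()
    ferry_routes = ferry_routes if ferry_routes is not None else load_ferry_routes()
    oop_splits = oop_splits if oop_splits is not None else load_oop_airport_splits()

    flight_by_code = dict(zip(airports["code"], airports["roundtrip_tco2e"]))
    split_value = {
        code: float((grp["share"] * grp["roundtrip_tco2e"]).sum())
        for code, grp in oop_splits.groupby("split_code")
    }
    route_km = dict(zip(ferry_routes["route"], ferry_routes["one_way_km"]))

    dupes = df.loc[df["city"].duplicated(), "city"].tolist()
    if dupes:
        raise ValidationError(f"duplicate city names: {dupes}")

    profiles: dict[str, CityProfile] = {}
    for i, row in df.iterrows():
        ferry = row["ferry_route"] if pd.notna(row["ferry_route"]) else None
        code = row["airport_code"] if pd.notna(row["airport_code"]) else None
        if code is not None:
            if code in flight_by_code:
                flight = float(flight_by_code[code])
            elif code in split_value:
                flight = split_value[code]
            else:
                raise ValidationError(f"row {i} ({row['city']}): unknown airport {code!r}")
        else:
            flight = 0.0
        try:
            profiles[row["city"]] = CityProfile(
                city=row["city"],
                region=row["region"],
                long_haul=bool(row["long_haul"]),
                visit_weight=float(row["visit_weight"]),
                drive_km_to_hospital=float(row["drive_km_to_hospital"]),
                ferry_route=ferry,
                drive_km_home_to_terminal=_num(row["drive_km_home_to_terminal"]),
                drive_km_terminal_to_hospital=_num(row["drive_km_terminal_to_hospital"]),
                ferry_route_km=float(route_km[ferry]) if ferry is not None else 0.0,
                airport_code=code,
                drive_km_home_to_airport=_num(row["drive_km_home_to_airport"]),
                drive_km_airport_to_hospital=_num(row["drive_km_airport_to_hospital"]),
                flight_roundtrip_tco2e_per_person=flight,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return profiles


def _num(value) -> float:
    return float(value) if pd.notna(value) else 0.0


def region_for_city(city: str, profiles: Mapping[str, CityProfile]) -> str:
    """Region of a city; unmapped and 'unidentified' cities resolve to Unknown."""
    if city in profiles:
        return profiles[city].region
    return "Unknown"
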