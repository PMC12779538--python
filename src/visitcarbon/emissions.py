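"""Per-visit CO2e equations for driving, ferrying, flying and virtual visits.

All four modes are costed per visit in metric tons CO2e:

* driving — one vehicle, round trip: ``km_one_way × g/km × 2`` (no people
  multiplier; the factor is per vehicle);
* ferrying — per passenger, round trip: ``kg/passenger-km × route_km ×
  travellers × 2``;
* flying — a published per-person round-trip footprint times the number of
  travellers;
* virtual — internet intensity: ``g/GB × GB/h × hours`` (63.7 g with the
  defaults of 45.5 g/GB, 1.4 GB/h and a one-hour visit).

A patient is assumed to travel with one accompanying adult, so
``travellers_per_visit`` defaults to 2; it scales ferry and flight emissions
but not driving (same vehicle) or virtual visits.

Arithmetic is done in grams internally and converted to metric tons at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from . import fleet
from .errors import InvalidInputError

G_PER_TON = 1e6
KG_PER_TON = 1e3


def _default_drive_factor() -> float:
    # fleet-weighted BC factor, unrounded (rounds to 259 g/km)
    return fleet.weighted_fleet_factor(fleet.load_fleet_table())


@dataclass(frozen=True)
class EmissionFactors:
    """The tunable constants of the four per-visit equations."""

    drive_gco2e_per_km: float = field(default_factory=_default_drive_factor)
    ferry_kgco2e_per_passenger_km: float = 0.11286
    internet_gco2e_per_gb: float = 45.5
    internet_gb_per_hour: float = 1.4
    virtual_visit_hours: float = 1.0
    travellers_per_visit: int = 2

    def __post_init__(self):
        for name in (
            "drive_gco2e_per_km",
            "ferry_kgco2e_per_passenger_km",
            "internet_gco2e_per_gb",
            "internet_gb_per_hour",
            "virtual_visit_hours",
        ):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if self.travellers_per_visit < 1:
            raise InvalidInputError("travellers_per_visit must be >= 1")

    @classmethod
    def from_file(cls, path) -> "EmissionFactors":
        """Load factors from a YAML/JSON mapping; absent fields keep defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise InvalidInputError(f"unknown factor fields: {sorted(unknown)}")
        return cls(**data)

    def with_(self, **kwargs) -> "EmissionFactors":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TripLegs:
    """The legs of one in-person trip variant (all distances one-way km).

    ``drive_km_total`` sums every road segment of the variant (home→hospital,
    or home→terminal plus terminal→hospital, or home→airport plus
    airport→hospital). At most one of the ferry and flight legs may be
    nonzero: a single mode variant never both ferries and flies.
    """

    drive_km_total: float = 0.0
    ferry_route_km: float = 0.0
    flight_roundtrip_tco2e_per_person: float = 0.0

    def __post_init__(self):
        for name in (
            "drive_km_total",
            "ferry_route_km",
            "flight_roundtrip_tco2e_per_person",
        ):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")
        if self.ferry_route_km > 0 and self.flight_roundtrip_tco2e_per_person > 0:
            raise InvalidInputError(
                "a single trip variant cannot have both ferry and flight legs"
            )


def drive_emission(distance_one_way_km: float, f: EmissionFactors) -> float:
    """Round-trip driving CO2e in metric tons for one vehicle."""
    if distance_one_way_km < 0:
        raise InvalidInputError("distance must be non-negative")
    grams = distance_one_way_km * f.drive_gco2e_per_km * 2.0
    return grams / G_PER_TON


def ferry_emission(route_one_way_km: float, f: EmissionFactors) -> float:
    """Round-trip ferry CO2e in metric tons for all travellers."""
    if route_one_way_km < 0:
        raise InvalidInputError("route distance must be non-negative")
    kg = (
        f.ferry_kgco2e_per_passenger_km
        * route_one_way_km
        * f.travellers_per_visit
        * 2.0
    )
    return kg / KG_PER_TON


def flight_emission(roundtrip_tco2e_per_person: float, f: EmissionFactors) -> float:
    """Round-trip flight CO2e in metric tons for all travellers."""
    if roundtrip_tco2e_per_person < 0:
        raise InvalidInputError("flight footprint must be non-negative")
    return roundtrip_tco2e_per_person * f.travellers_per_visit


def virtual_emission(f: EmissionFactors) -> float:
    """CO2e of one virtual visit in metric tons (city- and season-independent)."""
    grams = f.internet_gco2e_per_gb * f.internet_gb_per_hour * f.virtual_visit_hours
    return grams / G_PER_TON


def in_person_emission(legs: TripLegs, f: EmissionFactors) -> float:
    """Total CO2e of one in-person visit: strictly additive over its legs."""
    return (
        drive_emission(legs.drive_km_total, f)
        + ferry_emission(legs.ferry_route_km, f)
        + flight_emission(legs.flight_roundtrip_tco2e_per_person, f)
    )
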