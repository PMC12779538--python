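"""Fleet-weighted average driving emission factor.

The per-vehicle driving intensity is the registration-count-weighted mean of
per-fuel-type CO2e intensities (g/km) over a provincial vehicle fleet. Fuel
types with no published intensity (propane, natural gas, hydrogen, ...) stay
in the denominator and contribute nothing to the numerator — the conservative
reading of a weighted average over *all* registered vehicles.

The factor is carried unrounded through the pipeline; rounding to whole g/km
happens only at display time.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import InvalidInputError, ValidationError

FLEET_COLUMNS = ["fuel_type", "vehicle_count", "gco2e_per_km"]


def load_fleet_table(path=None) -> pd.DataFrame:
    """Read a fleet table CSV (header fuel_type,vehicle_count,gco2e_per_km).

    An empty gco2e_per_km cell means the fuel type has no published intensity.
    With no ``path``, returns the packaged BC 2021 registration table.
    """
    if path is None:
        path = resources.files("visitcarbon.data") / "fleet_bc_2021.csv"
    df = pd.read_csv(path)
    missing = set(FLEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"fleet table missing columns: {sorted(missing)}")
    if df["fuel_type"].duplicated().any():
        dupes = df.loc[df["fuel_type"].duplicated(), "fuel_type"].tolist()
        raise ValidationError(f"duplicate fuel types: {dupes}")
    validate_fleet_table(df)
    return df


def validate_fleet_table(fleet: pd.DataFrame) -> None:
    if len(fleet) == 0:
        raise InvalidInputError("fleet table is empty")
    counts = fleet["vehicle_count"]
    factors = fleet["gco2e_per_km"]
    if (counts < 0).any():
        raise InvalidInputError("vehicle_count must be non-negative")
    if (factors.dropna() < 0).any():
        raise InvalidInputError("gco2e_per_km must be non-negative")
    present = factors.notna() & (counts > 0)
    if not present.any():
        raise InvalidInputError(
            "fleet needs at least one fuel type with vehicles and a published intensity"
        )


def weighted_fleet_factor(fleet: pd.DataFrame) -> float:
    """Count-weighted mean driving intensity in g CO2e per vehicle-km.

    Rows with an absent intensity contribute 0 g/km but keep their vehicles in
    the denominator. Raises :class:`InvalidInputError` on an empty table, a
    zero total count, or negative inputs.
    """
    validate_fleet_table(fleet)
    total = float(fleet["vehicle_count"].sum())
    if total <= 0:
        raise InvalidInputError("total vehicle count is zero")
    numerator = float(
        (fleet["vehicle_count"] * fleet["gco2e_per_km"].fillna(0.0)).sum()
    )
    return numerator / total


def display_factor(gco2e_per_km: float) -> int:
    """Round a driving factor to whole g/km for display."""
    return int(round(gco2e_per_km))
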