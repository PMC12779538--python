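"""Mode-share scenarios and expected per-visit / total emissions under each.

A scenario assigns every (region-group, season) cell a (drive share, fly
share) pair summing to 1, optionally with a virtual-share override that
raises each region's virtual fraction to a target before travel is costed.

The four built-ins:

* ``realistic`` — Northern and Interior long-haul cities drive 90%/fly 10% in
  summer and split 50/50 in winter; Island/Coast and Mainland/Southwest
  always drive (island trips include the ferry); out-of-province always
  flies.
* ``winter_flying`` — realistic, but Northern/Interior long-haul cells fly
  100% in winter.
* ``winter_driving`` — all BC cells drive 100% in winter (out-of-province
  still flies).
* ``virtual_40`` — realistic shares with the virtual share raised to 40% in
  every region (raise-only: regions already at or above 40% are untouched).

Cities in Northern/Interior groups that are not flagged ``long_haul`` (closer
than Williams Lake / Kamloops / Kelowna) drive 100% in every scenario. A
positive fly share for a city with no airport falls back to driving with a
logged warning rather than failing the run. Unknown-region visits get zero
travel emissions (virtual visits still cost their internet footprint) and are
reported on a separate line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd
import yaml

from . import emissions
from ._apportion import largest_remainder
from .emissions import EmissionFactors
from .errors import InvalidInputError, ValidationError
from .geography import CityProfile, Season, legs_for_mode, region_for_city, season_for_quarter
from .reporting import EmissionReport
from .visits import VISIT_COLUMNS, validate_visit_table

logger = logging.getLogger(__name__)

GROUPS = ("Northern", "Interior", "Island/Coast", "Mainland/Southwest", "OutOfProvince")

_REGION_GROUP = {
    "Nechako": "Northern",
    "Cariboo": "Northern",
    "Northeast": "Northern",
    "North Coast": "Northern",
    "Kootenay": "Interior",
    "Thompson-Okanagan": "Interior",
    "Vancouver Island/Coast": "Island/Coast",
    "Mainland/Southwest": "Mainland/Southwest",
    "Out of Province": "OutOfProvince",
}


def group_for_region(region: str) -> Optional[str]:
    """Scenario region-group for an economic region; None for Unknown."""
    if region == "Unknown":
        return None
    try:
        return _REGION_GROUP[region]
    except KeyError:
        raise InvalidInputError(f"region {region!r} resolves to no scenario group") from None


@dataclass(frozen=True)
class ModeShareScenario:
    """Named mapping (region-group, season) → (drive share, fly share)."""

    name: str
    shares: Mapping[tuple[str, Season], tuple[float, float]]
    virtual_share_override: Optional[float] = None

    def __post_init__(self):
        expected = {(g, s) for g in GROUPS for s in Season}
        got = set(self.shares)
        if got != expected:
            raise ValidationError(
                f"scenario {self.name!r}: share cells must cover every "
                f"(group, season); missing {sorted(expected - got)}"
            )
        for cell, (drive, fly) in self.shares.items():
            if not (0.0 <= drive <= 1.0 and 0.0 <= fly <= 1.0):
                raise ValidationError(f"scenario {self.name!r} {cell}: shares outside [0,1]")
            if abs(drive + fly - 1.0) > 1e-9:
                raise ValidationError(
                    f"scenario {self.name!r} {cell}: drive+fly must sum to 1"
                )
        v = self.virtual_share_override
        if v is not None and not (0.0 <= v <= 1.0):
            raise ValidationError(f"scenario {self.name!r}: virtual override outside [0,1]")

    def share(self, group: str, season: Season) -> tuple[float, float]:
        return self.shares[(group, season)]

    def with_override(self, target: float, suffix: str = "") -> "ModeShareScenario":
        return ModeShareScenario(
            name=suffix or self.name,
            shares=dict(self.shares),
            virtual_share_override=target,
        )


def _shares(
    northern_summer, northern_winter, interior_summer=None, interior_winter=None
) -> dict:
    interior_summer = interior_summer or northern_summer
    interior_winter = interior_winter or northern_winter
    cells = {}
    for season in Season:
        cells[("Island/Coast", season)] = (1.0, 0.0)
        cells[("Mainland/Southwest", season)] = (1.0, 0.0)
        cells[("OutOfProvince", season)] = (0.0, 1.0)
    cells[("Northern", Season.SUMMER)] = northern_summer
    cells[("Northern", Season.WINTER)] = northern_winter
    cells[("Interior", Season.SUMMER)] = interior_summer
    cells[("Interior", Season.WINTER)] = interior_winter
    return cells


def builtin_scenarios() -> dict[str, ModeShareScenario]:
    """The four named base scenarios."""
    realistic = ModeShareScenario("realistic", _shares((0.9, 0.1), (0.5, 0.5)))
    winter_flying = ModeShareScenario("winter_flying", _shares((0.9, 0.1), (0.0, 1.0)))
    winter_driving = ModeShareScenario("winter_driving", _shares((0.9, 0.1), (1.0, 0.0)))
    virtual_40 = realistic.with_override(0.40, "virtual_40")
    return {
        "realistic": realistic,
        "winter_flying": winter_flying,
        "winter_driving": winter_driving,
        "virtual_40": virtual_40,
    }


def builtin_scenario_suite() -> list[ModeShareScenario]:
    """The four base scenarios plus the two combined ones."""
    base = builtin_scenarios()
    return [
        base["realistic"],
        base["winter_driving"],
        base["winter_flying"],
        base["virtual_40"],
        base["winter_driving"].with_override(0.40, "virtual_40+winter_driving"),
        base["winter_flying"].with_override(0.40, "virtual_40+winter_flying"),
    ]


def scenarios_to_yaml(scenarios: Iterable[ModeShareScenario], path) -> None:
    doc = {}
    for sc in scenarios:
        doc[sc.name] = {
            "shares": {
                f"{group}|{season.value}": [drive, fly]
                for (group, season), (drive, fly) in sorted(
                    sc.shares.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
                )
            },
            "virtual_share_override": sc.virtual_share_override,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def scenarios_from_yaml(path) -> dict[str, ModeShareScenario]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for name, spec in doc.items():
        shares = {}
        for key, (drive, fly) in spec["shares"].items():
            group, season = key.split("|")
            shares[(group, Season(season))] = (float(drive), float(fly))
        out[name] = ModeShareScenario(
            name=name,
            shares=shares,
            virtual_share_override=spec.get("virtual_share_override"),
        )
    return out


def expected_visit_emission(
    p: CityProfile,
    season: Season,
    scenario: ModeShareScenario,
    f: Optional[EmissionFactors] = None,
) -> float:
    """Share-weighted (convex) mean of the city's pure-mode trip emissions, in t."""
    f = f if f is not None else EmissionFactors()
    group = group_for_region(p.region)
    if group is None:
        raise InvalidInputError(
            f"{p.city}: Unknown region has no travel assignment"
        )
    drive_share, fly_share = scenario.share(group, season)
    # non-long-haul Northern/Interior cities always drive
    if group in ("Northern", "Interior") and not p.long_haul:
        drive_share, fly_share = 1.0, 0.0
    if fly_share > 0.0 and p.airport_code is None:
        logger.warning(
            "%s: fly share %.0f%% but no airport; falling back to driving",
            p.city,
            100 * fly_share,
        )
        drive_share, fly_share = 1.0, 0.0
    total = drive_share * emissions.in_person_emission(legs_for_mode(p, "drive"), f)
    if fly_share > 0.0:
        total += fly_share * emissions.in_person_emission(legs_for_mode(p, "fly"), f)
    return total


def apply_virtual_share(
    visits: pd.DataFrame,
    target: float,
    profiles: Mapping[str, CityProfile],
) -> pd.DataFrame:
    """Raise each region's virtual fraction to ``target``, never lowering it.

    Within a region whose virtual fraction is below target, in-person counts
    are reclassified to virtual proportionally across (city, quarter) cells
    with largest-remainder rounding, so the region lands as close to the
    target as integer counts allow. The grand total is conserved exactly.
    """
    if not (0.0 <= target <= 1.0):
        raise InvalidInputError("virtual share target must lie in [0, 1]")
    validate_visit_table(visits)
    if len(visits) == 0:
        return visits.copy()

    df = visits.copy().reset_index(drop=True)
    df["_region"] = [region_for_city(c, profiles) for c in df["city"]]

    moved_frames = []
    for _, grp in df.groupby("_region", sort=False):
        total = int(grp["count"].sum())
        virtual_now = int(grp.loc[grp["modality"] == "virtual", "count"].sum())
        want = int(round(target * total))
        need = want - virtual_now
        if need <= 0:
            continue
        cells = grp[grp["modality"] == "in-person"]
        quotas = largest_remainder(cells["count"].to_numpy(), need)
        moved = cells.loc[quotas > 0, ["city", "fiscal_quarter"]].copy()
        moved["count"] = quotas[quotas > 0]
        moved_frames.append(moved)

    if not moved_frames:
        return visits.copy()
    moved = pd.concat(moved_frames, ignore_index=True)

    df = df.drop(columns="_region")
    # subtract from in-person cells, add to matching virtual cells
    key = ["city", "fiscal_quarter"]
    delta = moved.set_index(key)["count"]
    inp = df["modality"] == "in-person"
    idx = pd.MultiIndex.from_frame(df[key])
    shift = pd.Series(idx.map(delta).fillna(0).astype(int).to_numpy(), index=df.index)
    df.loc[inp, "count"] = df.loc[inp, "count"] - shift[inp]

    virt = moved.assign(modality="virtual")
    out = pd.concat([df, virt[VISIT_COLUMNS]], ignore_index=True)
    out = (
        out.groupby(["city", "fiscal_quarter", "modality"], as_index=False, sort=False)[
            "count"
        ].sum()
    )
    out = out[out["count"] > 0].reset_index(drop=True)
    validate_visit_table(out)
    if int(out["count"].sum()) != int(visits["count"].sum()):
        raise AssertionError("virtual reallocation must conserve the grand total")
    return out


def scenario_total(
    visits: pd.DataFrame,
    profiles: Mapping[str, CityProfile],
    scenario: ModeShareScenario,
    f: Optional[EmissionFactors] = None,
) -> EmissionReport:
    """Total CO2e of a visit table under one scenario, by region.

    In-person rows cost ``count × expected_visit_emission`` for their city and
    season; virtual rows cost ``count × virtual_emission``. Unknown-region
    in-person visits carry zero travel emissions.
    """
    f = f if f is not None else EmissionFactors()
    validate_visit_table(visits)

    if scenario.virtual_share_override is not None:
        visits = apply_virtual_share(visits, scenario.virtual_share_override, profiles)

    named = set(visits["city"]) - {"unidentified"}
    missing = sorted(named - set(profiles))
    if missing:
        raise InvalidInputError(f"no city profile for: {missing}")

    e_virtual = emissions.virtual_emission(f)
    per_region: dict[str, dict[str, float]] = {}
    for row in visits.itertuples(index=False):
        region = region_for_city(row.city, profiles)
        bucket = per_region.setdefault(region, {"in_person_t": 0.0, "virtual_t": 0.0})
        if row.modality == "virtual":
            bucket["virtual_t"] += row.count * e_virtual
        elif region == "Unknown":
            bucket["in_person_t"] += 0.0  # no distance assignable
        else:
            season = season_for_quarter(row.fiscal_quarter)
            bucket["in_person_t"] += row.count * expected_visit_emission(
                profiles[row.city], season, scenario, f
            )

    rows = pd.DataFrame(
        [
            {
                "region": region,
                "in_person_t": vals["in_person_t"],
                "virtual_t": vals["virtual_t"],
                "total_t": vals["in_person_t"] + vals["virtual_t"],
            }
            for region, vals in sorted(per_region.items())
        ],
        columns=["region", "in_person_t", "virtual_t", "total_t"],
    )
    metadata = {
        "scenario": scenario.name,
        "virtual_share_override": scenario.virtual_share_override,
        "drive_gco2e_per_km": f.drive_gco2e_per_km,
        "travellers_per_visit": f.travellers_per_visit,
        "unknown_region_zero_travel": "Unknown" in per_region,
    }
    return EmissionReport(scenario=scenario.name, rows=rows, metadata=metadata)


def compare_scenarios(baseline: EmissionReport, alt: EmissionReport) -> float:
    """Percent change of ``alt`` vs ``baseline`` grand totals."""
    b = baseline.grand_total_t
    if b <= 0:
        raise InvalidInputError("baseline total must be positive to compare")
    return 100.0 * (alt.grand_total_t - b) / b
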