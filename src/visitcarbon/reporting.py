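"""Emission reports: per-region totals, per-capita normalisation, scenario matrices.

Totals are displayed as whole metric tons; machine-readable output (JSON/CSV)
keeps full precision. Unknown-region visits carry zero travel emissions and
are kept on their own line so totals can be read with or without them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from .errors import InvalidInputError, ValidationError

REPORT_COLUMNS = ["region", "in_person_t", "virtual_t", "total_t"]


@dataclass
class EmissionReport:
    """Per-region and total CO2e (metric tons) for one scenario run."""

    scenario: str
    rows: pd.DataFrame  # region, in_person_t, virtual_t, total_t
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(REPORT_COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValidationError(f"report rows missing columns: {sorted(missing)}")
        bad = (
            (self.rows["in_person_t"] + self.rows["virtual_t"] - self.rows["total_t"])
            .abs()
            .gt(1e-9)
        )
        if bad.any():
            raise ValidationError("row totals must equal in-person + virtual")

    @property
    def grand_total_t(self) -> float:
        return float(self.rows["total_t"].sum())

    @property
    def virtual_total_t(self) -> float:
        return float(self.rows["virtual_t"].sum())

    def region_total(self, region: str) -> float:
        match = self.rows.loc[self.rows["region"] == region, "total_t"]
        return float(match.iloc[0]) if len(match) else 0.0

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "metadata": self.metadata,
            "grand_total_t": self.grand_total_t,
            "rows": self.rows[REPORT_COLUMNS].to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EmissionReport":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            scenario=data["scenario"],
            rows=pd.DataFrame(data["rows"], columns=REPORT_COLUMNS),
            metadata=data.get("metadata", {}),
        )

    def to_csv(self, path, populations: Optional[Mapping[str, int]] = None) -> None:
        """Write region,in_person_t,virtual_t,total_t[,per_capita_t]."""
        out = self.rows[REPORT_COLUMNS].copy()
        if populations is not None:
            pc = per_capita(self, populations)
            out["per_capita_t"] = [pc.get(r) for r in out["region"]]
        out.to_csv(path, index=False)


def per_capita(
    report: EmissionReport, populations: Mapping[str, int]
) -> dict[str, float]:
    """Region total / region population, in t CO2e per person.

    Regions absent from the population table (or with a non-positive entry)
    are flagged in ``report.metadata['per_capita_missing']`` and omitted.
    """
    out: dict[str, float] = {}
    missing: list[str] = []
    for _, row in report.rows.iterrows():
        pop = populations.get(row["region"], 0)
        if pop and pop > 0:
            out[row["region"]] = float(row["total_t"]) / pop
        else:
            missing.append(row["region"])
    report.metadata["per_capita_missing"] = missing
    return out


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (display convention)."""
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def scenario_matrix(visits, profiles, scenarios, factors=None) -> pd.DataFrame:
    """One row per scenario: total tCO2e and percent change vs 'realistic'.

    ``scenarios`` is an iterable of ModeShareScenario (defaults to the
    six-member built-in suite). Duplicate names and a missing realistic
    baseline are errors.
    """
    from .scenarios import builtin_scenario_suite, compare_scenarios, scenario_total

    if scenarios is None:
        scenarios = builtin_scenario_suite()
    scenarios = list(scenarios)
    names = [sc.name for sc in scenarios]
    if len(set(names)) != len(names):
        raise InvalidInputError(f"duplicate scenario names in {names}")
    if "realistic" not in names:
        raise InvalidInputError("scenario matrix requires a 'realistic' baseline")

    reports = {sc.name: scenario_total(visits, profiles, sc, factors) for sc in scenarios}
    baseline = reports["realistic"]
    records = []
    for name in names:
        total = reports[name].grand_total_t
        if name == "realistic":
            pct = None
            pct_display = None
        else:
            pct = compare_scenarios(baseline, reports[name])
            pct_display = round_half_away(pct)
        records.append(
            {
                "scenario": name,
                "total_t": total,
                "pct_change_vs_realistic": pct,
                "pct_change_display": pct_display,
            }
        )
    out = pd.DataFrame.from_records(records)
    out["pct_change_display"] = out["pct_change_display"].astype("Int64")
    return out
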