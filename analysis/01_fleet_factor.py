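#!/usr/bin/env python
"""Derive the fleet-weighted driving emission factor for the province.

Weights each fuel type's average CO2e intensity (g/km) by its registration
count; fuel types with no published intensity stay in the denominator.
Writes results/fleet_factor.json.
"""

import json
from pathlib import Path

import visitcarbon as vc

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    fleet = vc.load_fleet_table()
    factor = vc.weighted_fleet_factor(fleet)
    print(fleet.to_string(index=False))
    print(f"\nfleet-weighted driving factor: {factor:.3f} g CO2e/km "
          f"(display: {vc.display_factor(factor)} g/km)")
    OUT.mkdir(exist_ok=True)
    (OUT / "fleet_factor.json").write_text(json.dumps({
        "gco2e_per_km": factor,
        "gco2e_per_km_display": vc.display_factor(factor),
        "total_vehicles": int(fleet["vehicle_count"].sum()),
    }, indent=2) + "\n")
    print(f"wrote {OUT / 'fleet_factor.json'}")


if __name__ == "__main__":
    main()
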