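#!/usr/bin/env python
"""Cost the fixture year under the realistic scenario.

Produces the per-region emission report (in-person vs virtual split) and the
per-capita normalisation, writing results/realistic_report.{csv,json}.
"""

from pathlib import Path

import visitcarbon as vc

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    profiles = vc.load_city_profiles()
    visits = vc.read_visits(OUT / "visits_fixture.csv")
    realistic = vc.builtin_scenarios()["realistic"]
    factors = vc.EmissionFactors()

    report = vc.scenario_total(visits, profiles, realistic, factors)
    populations = vc.load_populations()
    pc = vc.per_capita(report, populations)

    print(report.rows.to_string(index=False, float_format=lambda x: f"{x:,.1f}"))
    print(f"\ngrand total: {report.grand_total_t:,.0f} t CO2e "
          f"(virtual visits: {report.virtual_total_t:,.1f} t)")
    print("\nper-capita t CO2e/person:")
    for region, value in sorted(pc.items(), key=lambda kv: -kv[1]):
        print(f"  {region:<24} {value:.4f}")
    print(f"(no population on file for: {report.metadata['per_capita_missing']})")

    report.to_csv(OUT / "realistic_report.csv", populations=populations)
    report.to_json(OUT / "realistic_report.json")
    print(f"\nwrote {OUT / 'realistic_report.csv'} and .json")


if __name__ == "__main__":
    main()
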