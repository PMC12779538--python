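#!/usr/bin/env python
"""Compare the six built-in scenarios on the fixture year.

Evaluates realistic, winter driving, winter flying, 40% virtual, and the two
combined scenarios, reporting each total and its percent change against the
realistic baseline. Writes results/scenario_matrix.csv.
"""

from pathlib import Path

import pandas as pd

import visitcarbon as vc

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    OUT.mkdir(exist_ok=True)
    profiles = vc.load_city_profiles()
    visits = vc.read_visits(OUT / "visits_fixture.csv")
    matrix = vc.scenario_matrix(visits, profiles, vc.builtin_scenario_suite())

    for row in matrix.itertuples(index=False):
        change = "n/a" if pd.isna(row.pct_change_display) else f"{int(row.pct_change_display):+d}%"
        print(f"{row.scenario:<28} {row.total_t:>12,.0f} t   {change}")

    matrix.to_csv(OUT / "scenario_matrix.csv", index=False)
    print(f"\nwrote {OUT / 'scenario_matrix.csv'}")


if __name__ == "__main__":
    main()
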