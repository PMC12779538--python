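#!/usr/bin/env python
"""Build the visit tables every later step consumes.

Two tables go to results/: the deterministic fixture reproducing the
published per-region totals and modality splits (397,962 visits, ~19%
virtual), and a seeded stochastic draw with the same marginals for
sensitivity checks.
"""

from pathlib import Path

import visitcarbon as vc

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 2021


def summarize(name, visits, profiles):
    total = int(visits["count"].sum())
    virtual = int(visits.loc[visits["modality"] == "virtual", "count"].sum())
    print(f"{name}: {total} visits, {virtual / total:.1%} virtual, {len(visits)} rows")


def main():
    OUT.mkdir(exist_ok=True)
    profiles = vc.load_city_profiles()

    fixture = vc.fixture_table6(profiles)
    vc.write_visits(fixture, OUT / "visits_fixture.csv")
    summarize("deterministic fixture", fixture, profiles)

    drawn = vc.generate_visits(vc.GeneratorConfig(seed=SEED), profiles)
    vc.write_visits(drawn, OUT / "visits_simulated.csv")
    summarize(f"simulated (seed {SEED})", drawn, profiles)

    print(f"wrote {OUT / 'visits_fixture.csv'} and {OUT / 'visits_simulated.csv'}")


if __name__ == "__main__":
    main()
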