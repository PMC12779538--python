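"""Synthetic visit tables with the marginal structure of the study year.

The real hospital visit records are not public; what is published is the
per-region visit totals and in-person/virtual percentages for fiscal year
2021/22 (397,962 visits, 19% virtual) and the privacy rule that any home
city/town with fewer than five visits is recoded to "unidentified".

The generator reproduces exactly those marginals: regions receive their
configured totals by largest-remainder apportionment, and within a region
visits fall multinomially across (city, quarter, modality) cells — city
weights times quarter weights, with modality at the region's virtual
fraction. The per-city distribution inside each region is synthetic
(weights from the packaged city fixture); quarter weights default to
uniform because no seasonal visit-volume data was published.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from ._apportion import largest_remainder
from .errors import ConfigurationError, InvalidInputError
from .geography import QUARTERS, UNIDENTIFIED, CityProfile, load_city_profiles
from .visits import VISIT_COLUMNS, validate_visit_table

#: Published per-region visit totals for fiscal year 2021/22 (sum 397,962).
REGION_VISITS: dict[str, int] = {
    "Mainland/Southwest": 345727,
    "Vancouver Island/Coast": 16272,
    "Thompson-Okanagan": 15414,
    "Cariboo": 5717,
    "North Coast": 3294,
    "Kootenay": 2826,
    "Out of Province": 2737,
    "Northeast": 2443,
    "Nechako": 1830,
    "Unknown": 1702,
}

#: Published per-region virtual-visit fractions (whole percentages).
REGION_VIRTUAL_FRACTION: dict[str, float] = {
    "Mainland/Southwest": 0.16,
    "Vancouver Island/Coast": 0.39,
    "Thompson-Okanagan": 0.37,
    "Cariboo": 0.35,
    "North Coast": 0.28,
    "Kootenay": 0.40,
    "Out of Province": 0.24,
    "Northeast": 0.33,
    "Nechako": 0.30,
    "Unknown": 0.27,
}

TOTAL_VISITS = 397962
SUPPRESSION_THRESHOLD = 5


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic generator; defaults are the published marginals."""

    total_visits: int = TOTAL_VISITS
    region_shares: Mapping[str, float] = field(default_factory=lambda: dict(REGION_VISITS))
    virtual_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(REGION_VIRTUAL_FRACTION)
    )
    city_weights: Optional[Mapping[str, Mapping[str, float]]] = None  # region -> city -> w
    quarter_weights: Mapping[str, float] = field(
        default_factory=lambda: {q: 0.25 for q in QUARTERS}
    )
    seed: int = 0

    def __post_init__(self):
        if self.total_visits < 0:
            raise InvalidInputError("total_visits must be non-negative")
        for region, frac in self.virtual_fractions.items():
            if not (0.0 <= frac <= 1.0):
                raise InvalidInputError(f"{region}: virtual fraction outside [0,1]")
        if set(self.region_shares) - set(self.virtual_fractions):
            raise InvalidInputError("every region with a share needs a virtual fraction")
        if abs(sum(self.quarter_weights.get(q, 0.0) for q in QUARTERS)) <= 0:
            raise InvalidInputError("quarter weights must have a positive sum")


def _default_city_weights(
    profiles: Mapping[str, CityProfile]
) -> dict[str, dict[str, float]]:
    weights: dict[str, dict[str, float]] = {}
    for p in profiles.values():
        weights.setdefault(p.region, {})[p.city] = p.visit_weight
    return weights


def suppress_small_cities(visits: pd.DataFrame) -> pd.DataFrame:
    """Recode any named city with a table-wide total below 5 to "unidentified".

    The grand total is conserved; suppressed counts merge into the
    "unidentified" rows keyed by (quarter, modality).
    """
    if len(visits) == 0:
        return visits.copy()
    totals = visits.groupby("city")["count"].sum()
    small = set(totals[totals < SUPPRESSION_THRESHOLD].index) - {UNIDENTIFIED}
    if not small:
        return visits.copy()
    out = visits.copy()
    out.loc[out["city"].isin(small), "city"] = UNIDENTIFIED
    out = out.groupby(["city", "fiscal_quarter", "modality"], as_index=False, sort=False)[
        "count"
    ].sum()
    return out.reset_index(drop=True)


def generate_visits(
    cfg: Optional[GeneratorConfig] = None,
    profiles: Optional[Mapping[str, CityProfile]] = None,
) -> pd.DataFrame:
    """Draw a seeded synthetic visit table.

    Region totals follow the configured shares exactly (largest remainder);
    within each region, counts fall multinomially across (city, quarter,
    modality). Small cities are then suppressed. Deterministic given
    ``cfg.seed``; the seed is recorded in ``df.attrs``.
    """
    cfg = cfg or GeneratorConfig()
    profiles = profiles if profiles is not None else load_city_profiles()
    city_weights = cfg.city_weights or _default_city_weights(profiles)

    known = set(profiles) | {UNIDENTIFIED}
    for region, cities in city_weights.items():
        unknown = set(cities) - known
        if unknown:
            raise ConfigurationError(
                f"{region}: city weights reference unknown cities {sorted(unknown)}"
            )

    regions = list(cfg.region_shares)
    region_counts = largest_remainder(
        [cfg.region_shares[r] for r in regions], cfg.total_visits
    )
    rng = np.random.default_rng(cfg.seed)
    qw = np.array([cfg.quarter_weights.get(q, 0.0) for q in QUARTERS], dtype=float)
    qw = qw / qw.sum()

    records = []
    for region, n in zip(regions, region_counts):
        if n == 0:
            continue
        cities = city_weights.get(region) or {UNIDENTIFIED: 1.0}
        names = list(cities)
        cw = np.array([cities[c] for c in names], dtype=float)
        if cw.sum() <= 0:
            raise ConfigurationError(f"{region}: city weights must have a positive sum")
        cw = cw / cw.sum()
        v = cfg.virtual_fractions[region]
        # cell probabilities over cities × quarters × {in-person, virtual}
        probs = np.einsum("c,q,m->cqm", cw, qw, np.array([1.0 - v, v])).ravel()
        draws = rng.multinomial(int(n), probs).reshape(len(names), 4, 2)
        for ci, city in enumerate(names):
            for qi, quarter in enumerate(QUARTERS):
                for mi, modality in enumerate(("in-person", "virtual")):
                    count = int(draws[ci, qi, mi])
                    if count:
                        records.append((city, quarter, modality, count))

    df = pd.DataFrame(records, columns=VISIT_COLUMNS)
    df = suppress_small_cities(df)
    validate_visit_table(df)
    df.attrs["seed"] = cfg.seed
    df.attrs["total_visits"] = cfg.total_visits
    return df


def fixture_table6(
    profiles: Optional[Mapping[str, CityProfile]] = None,
) -> pd.DataFrame:
    """The deterministic packaged table reproducing the published marginals.

    Each region's total is exact; its in-person/virtual split follows the
    printed whole percentages with largest-remainder rounding, then spreads
    across the region's fixture cities (by weight) and uniformly across the
    four fiscal quarters, largest remainder throughout. Sums to 397,962.
    """
    profiles = profiles if profiles is not None else load_city_profiles()
    city_weights = _default_city_weights(profiles)

    records = []
    for region, total in REGION_VISITS.items():
        v = REGION_VIRTUAL_FRACTION[region]
        virtual, in_person = largest_remainder([v, 1.0 - v], total)
        cities = city_weights.get(region) or {UNIDENTIFIED: 1.0}
        names = list(cities)
        cw = [cities[c] for c in names]
        for modality, m_total in (("in-person", in_person), ("virtual", virtual)):
            per_city = largest_remainder(cw, int(m_total))
            for city, c_total in zip(names, per_city):
                per_quarter = largest_remainder([1.0] * 4, int(c_total))
                for quarter, count in zip(QUARTERS, per_quarter):
                    if count:
                        records.append((city, quarter, modality, int(count)))

    df = pd.DataFrame(records, columns=VISIT_COLUMNS)
    df = suppress_small_cities(df)
    validate_visit_table(df)
    return df
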