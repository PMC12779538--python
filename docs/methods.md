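# Methods

## Model

The unit of account is one visit, costed in metric tons CO2e. In-person
visits decompose into legs; emissions are strictly additive over legs and
linear in distance/duration:

| mode    | equation (t/visit)                                   | basis        |
|---------|------------------------------------------------------|--------------|
| drive   | `d_km × g/km × 2 × 10⁻⁶`                             | per vehicle  |
| ferry   | `0.11286 kg/p-km × route_km × people × 2 × 10⁻³`     | per person   |
| fly     | `roundtrip_t/person × people` + airport road legs    | per person   |
| virtual | `g/GB × GB/h × h × 10⁻⁶`                             | per session  |

Arithmetic is carried in grams internally and converted to tons at the
reporting boundary. The driving equation deliberately has no occupancy
multiplier (one vehicle regardless of travellers), and the ferry-terminal and
airport road legs are costed with the same vehicle-based driving equation.
The virtual-visit defaults multiply out to 63.7 g per one-hour session; this
value is independent of city and season.

A visit's expected emission under a scenario is a convex combination of its
pure-mode costs: `drive_share × E_drive + fly_share × E_fly`, with shares
assigned per (region-group, season). Scenario totals are therefore linear in
the visit table, which makes the order of virtual reallocation and
mode-share substitution irrelevant for combined scenarios.

## Parameters

- `drive_gco2e_per_km` — registration-count-weighted mean of per-fuel-type
  intensities over the provincial fleet; 259.423 g/km unrounded from the
  packaged table, displayed as 259. Fuel types with no published intensity
  (196 vehicles) are kept in the denominator at zero numerator: both
  inclusion and exclusion round to 259 at fleet scale, and inclusion is the
  conservative reading of a weighted average over all registered vehicles.
- `ferry_kgco2e_per_passenger_km = 0.11286` — an all-passenger-type reference
  intensity; route-specific local values are not published.
- `internet_gco2e_per_gb = 45.5`, `internet_gb_per_hour = 1.4`,
  `virtual_visit_hours = 1` — midpoint internet carbon intensity and the
  upper end of 720p video bandwidth; one hour is a deliberate overestimate of
  typical visit length.
- `travellers_per_visit = 2` — a pediatric patient accompanied by one adult.
  Scales ferry and flight emissions only.

All are overridable via `EmissionFactors` or a YAML config.

## Geography and seasons

Fiscal quarters start April 1; Q1–Q2 map to summer, Q3–Q4 to winter. Region
groups for scenarios: Northern = {Nechako, Cariboo, Northeast, North Coast},
Interior = {Kootenay, Thompson-Okanagan}, plus Island/Coast,
Mainland/Southwest and Out of Province. The "long haul" qualifier (at or
beyond Williams Lake / Kamloops / Kelowna) is a per-city boolean in the
profile rather than being recomputed from distances, since the defining
distances are themselves inputs. Non-long-haul Northern/Interior cities
drive 100% in every scenario. Out-of-province cities resolve their flight
footprint through an airport-split table (equal shares across a province's
major airports); the packaged Alberta split is synthetic.

Island cities route through one of the three major ferry crossings, with
home→terminal and terminal→hospital road legs; short crossings (e.g. the
Sunshine Coast) are folded into plain driving distance. A city asked to fly
without an airport on file falls back to 100% driving with a logged warning
— failing the whole run over one city would hide the rest of the report.

Unknown-region visits (the "unidentified" small-cell bucket) get zero travel
emissions, since no distance is assignable; virtual visits from that bucket
still cost their internet footprint. They are reported on a separate line so
totals can be read with or without them.

## Scenarios

`realistic` is the baseline share table. `winter_flying` / `winter_driving`
flip the Northern/Interior winter cells to 0/100 and 100/0 (out-of-province
always flies). `virtual_40` raises each region's virtual fraction to 40% —
raise-only, so regions already at or above target are untouched; this
matches the framing of virtual care as a savings lever and never converts
virtual visits back into travel. The reallocation is integer-exact: the
region's shortfall is spread over its in-person (city, quarter) cells
proportionally with largest-remainder rounding, conserving the grand total
exactly. Percent changes against the realistic baseline are rounded
half-away-from-zero to whole percent at display time only.

## Synthetic visit tables

The generator emulates the published marginal structure of the study year:
397,962 visits, exact per-region totals (largest-remainder apportionment, so
apportionment error is under one visit per region), per-region virtual
fractions, and the rule that any named city with fewer than five visits is
recoded to "unidentified". Within a region, counts fall multinomially over
(city, quarter, modality) cells; city weights come from the packaged
fixture, and quarter weights default to uniform because no seasonal
visit-volume data was published. Draws are seeded and deterministic, with
the seed recorded in the table's metadata.

What the generator does **not** emulate: the true per-city distribution
(unknowable from published marginals), visit-type structure
(inpatient/outpatient/emergency), repeat visits by the same family, or
seasonal volume fluctuations. Passing tests on synthetic tables therefore
validate the accounting pipeline — equations, shares, reallocation,
aggregation — not the realism of any particular total. The deterministic
fixture's count-weighted virtual share is 18.6%, consistent with the
published rounded 19%.

## Numerical choices

- Emission factors and totals are floats; only display rounds (whole g/km,
  whole tons, whole percent, half away from zero).
- Largest-remainder ties break by cell position (stable argsort), so all
  apportionments are deterministic.
- Empty visit tables are valid and cost zero; a zero baseline total makes
  percent comparison an error rather than a NaN.
- Share cells must sum to 1 within 1e-9; report row identities hold to 1e-9 t.

## Design notes

- The driving factor is derived from the fleet table at runtime, never
  hard-coded; pinning it to the display value 259 is the caller's choice
  (the worked examples do, to match published arithmetic).
- Packaged distances are synthetic but chosen so the qualitative orderings
  hold: every long-haul city's fly-mode cost is below its drive-mode cost,
  hence winter_flying ≤ realistic ≤ winter_driving on the fixture, and
  per-capita burden ranks remote low-population regions far above the
  metropolitan region.
- Analysis drivers run on the deterministic fixture (240 rows, <1 s each);
  the property suite uses 1,000 randomized records for oracle equivalence
  and a full-size (397,962-visit) generator draw for marginal recovery.

## Limitations

Absolute fixture totals (≈11,400 t for the realistic scenario) depend on the
synthetic distances and are illustrative; only the desk-scale per-visit
numbers (259 g/km, 202 kg Kelowna round trip, 63.7 g virtual) and the
structural/sign results are reproducible claims. Walking, cycling, transit,
phone-vs-video virtual visits and multi-appointment trips are out of scope.
The ferry intensity is an international reference value; the out-of-province
flight values are invented placeholders.
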