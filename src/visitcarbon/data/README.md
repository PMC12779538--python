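# Packaged reference data

Published reference values, reproduced verbatim:

- `fleet_bc_2021.csv` — BC light-vehicle registrations (< 4535 kg) by fuel type with
  per-fuel-type average CO2e intensities (g/km); the `other` row has no published
  intensity and its cell is empty.
- `ferry_routes.csv` — the three major BC Ferries routes with one-way distances (km).
- `airports.csv` — per-person round-trip flight CO2e (metric tons) from each BC
  airport to Vancouver International (YVR).

Synthetic fixtures (plausible stand-ins; the underlying study inputs are not public):

- `city_profiles.csv` — a 30-city fixture. Road distances are illustrative one-way
  km, not routed distances (Kelowna is pinned at 390 km so the worked round-trip
  driving example reproduces). `long_haul` marks Northern/Interior cities at or
  beyond Williams Lake / Kamloops / Kelowna that receive fly shares in scenarios.
- `oop_airports.csv` — SYNTHETIC out-of-province airport split (Alberta: equal shares
  via Calgary and Edmonton) with invented round-trip flight values.
- `populations.csv` — approximate regional populations used only for per-capita
  normalisation.
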