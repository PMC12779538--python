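"""Mode-share scenarios: built-ins, convexity, virtual reallocation, totals."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import visitcarbon as vc
from visitcarbon.errors import InvalidInputError, ValidationError
from visitcarbon.geography import QUARTERS, Season
from visitcarbon.scenarios import group_for_region, scenarios_from_yaml, scenarios_to_yaml
from visitcarbon.visits import VISIT_COLUMNS


@pytest.fixture(scope="module")
def builtins():
    return vc.builtin_scenarios()


class TestBuiltins:
    @pytest.mark.parametrize(
        "name, group, season, expected",
        [
            ("realistic", "Northern", Season.SUMMER, (0.9, 0.1)),
            ("realistic", "Northern", Season.WINTER, (0.5, 0.5)),
            ("realistic", "Interior", Season.SUMMER, (0.9, 0.1)),
            ("realistic", "Mainland/Southwest", Season.WINTER, (1.0, 0.0)),
            ("realistic", "Island/Coast", Season.SUMMER, (1.0, 0.0)),
            ("realistic", "OutOfProvince", Season.WINTER, (0.0, 1.0)),
            ("winter_flying", "Northern", Season.WINTER, (0.0, 1.0)),
            ("winter_flying", "Interior", Season.SUMMER, (0.9, 0.1)),
            ("winter_driving", "Northern", Season.WINTER, (1.0, 0.0)),
            ("winter_driving", "OutOfProvince", Season.WINTER, (0.0, 1.0)),
        ],
    )
    def test_share_cells(self, builtins, name, group, season, expected):
        assert builtins[name].share(group, season) == expected

    def test_virtual_40_overrides_realistic_shares(self, builtins):
        v40 = builtins["virtual_40"]
        assert v40.virtual_share_override == pytest.approx(0.40)
        assert dict(v40.shares) == dict(builtins["realistic"].shares)

    def test_suite_has_six_unique_scenarios(self):
        suite = vc.builtin_scenario_suite()
        assert len({sc.name for sc in suite}) == 6

    def test_incomplete_shares_rejected(self, builtins):
        shares = dict(builtins["realistic"].shares)
        shares.pop(("Northern", Season.WINTER))
        with pytest.raises(ValidationError):
            vc.ModeShareScenario("broken", shares)

    def test_shares_must_sum_to_one(self, builtins):
        shares = dict(builtins["realistic"].shares)
        shares[("Northern", Season.WINTER)] = (0.5, 0.6)
        with pytest.raises(ValidationError):
            vc.ModeShareScenario("broken", shares)

    def test_yaml_round_trip(self, tmp_path, builtins):
        path = tmp_path / "scenarios.yaml"
        scenarios_to_yaml(builtins.values(), path)
        back = scenarios_from_yaml(path)
        assert set(back) == set(builtins)
        for name, sc in builtins.items():
            assert dict(back[name].shares) == dict(sc.shares)
            assert back[name].virtual_share_override == sc.virtual_share_override


def test_region_groups():
    assert group_for_region("Nechako") == "Northern"
    assert group_for_region("Cariboo") == "Northern"
    assert group_for_region("Kootenay") == "Interior"
    assert group_for_region("Thompson-Okanagan") == "Interior"
    assert group_for_region("Out of Province") == "OutOfProvince"
    assert group_for_region("Unknown") is None
    with pytest.raises(InvalidInputError):
        group_for_region("Narnia")


class TestExpectedVisitEmission:
    def test_fifty_fifty_is_midpoint_of_pure_modes(self, profiles, factors, builtins):
        p = profiles["Kelowna"]
        drive = vc.in_person_emission(vc.legs_for_mode(p, "drive"), factors)
        fly = vc.in_person_emission(vc.legs_for_mode(p, "fly"), factors)
        got = vc.expected_visit_emission(p, Season.WINTER, builtins["realistic"], factors)
        assert got == pytest.approx(0.5 * drive + 0.5 * fly, rel=1e-12)

    def test_pure_drive_share_equals_drive_mode(self, profiles, factors, builtins):
        p = profiles["Victoria"]
        drive = vc.in_person_emission(vc.legs_for_mode(p, "drive"), factors)
        for season in Season:
            got = vc.expected_visit_emission(p, season, builtins["realistic"], factors)
            assert got == pytest.approx(drive, rel=1e-12)

    def test_convexity_across_all_cities_and_scenarios(self, profiles, factors):
        """Expected emission lies between the pure-mode extremes everywhere."""
        for sc in vc.builtin_scenario_suite():
            for p in profiles.values():
                if p.region == "Unknown":
                    continue
                modes = [vc.in_person_emission(vc.legs_for_mode(p, "drive"), factors)]
                if p.airport_code is not None:
                    modes.append(
                        vc.in_person_emission(vc.legs_for_mode(p, "fly"), factors)
                    )
                for season in Season:
                    got = vc.expected_visit_emission(p, season, sc, factors)
                    assert min(modes) - 1e-12 <= got <= max(modes) + 1e-12

    def test_short_haul_interior_city_always_drives(self, profiles, factors, builtins):
        p = profiles["Merritt"]  # Interior but nearer than Kamloops/Kelowna
        drive = vc.in_person_emission(vc.legs_for_mode(p, "drive"), factors)
        for name in ("realistic", "winter_flying"):
            got = vc.expected_visit_emission(p, Season.WINTER, builtins[name], factors)
            assert got == pytest.approx(drive, rel=1e-12)

    def test_fly_share_without_airport_falls_back_to_driving(
        self, factors, builtins, caplog
    ):
        p = vc.CityProfile(
            city="Roadsend", region="Cariboo", long_haul=True, drive_km_to_hospital=600
        )
        with caplog.at_level(logging.WARNING):
            got = vc.expected_visit_emission(p, Season.WINTER, builtins["realistic"], factors)
        assert got == pytest.approx(vc.drive_emission(600, factors), rel=1e-12)
        assert "Roadsend" in caplog.text

    def test_unknown_region_rejected(self, factors, builtins):
        p = vc.CityProfile(city="unidentified", region="Unknown")
        with pytest.raises(InvalidInputError):
            vc.expected_visit_emission(p, Season.SUMMER, builtins["realistic"], factors)


def visits_frame(rows):
    return pd.DataFrame(rows, columns=VISIT_COLUMNS)


class TestApplyVirtualShare:
    def test_raises_84_16_split_to_60_40(self, profiles):
        v = visits_frame(
            [("Vancouver", "Q1", "in-person", 84), ("Vancouver", "Q1", "virtual", 16)]
        )
        out = vc.apply_virtual_share(v, 0.40, profiles)
        got = out.groupby("modality")["count"].sum()
        assert got["in-person"] == 60 and got["virtual"] == 40

    def test_region_already_at_target_untouched(self, profiles):
        v = visits_frame(
            [("Cranbrook", "Q2", "in-person", 60), ("Cranbrook", "Q2", "virtual", 40)]
        )
        out = vc.apply_virtual_share(v, 0.40, profiles)
        pd.testing.assert_frame_equal(
            out.sort_values(VISIT_COLUMNS).reset_index(drop=True),
            v.sort_values(VISIT_COLUMNS).reset_index(drop=True),
        )

    def test_target_outside_unit_interval_rejected(self, profiles, table6):
        with pytest.raises(InvalidInputError):
            vc.apply_virtual_share(table6, 1.5, profiles)

    @given(
        counts=st.lists(st.integers(1, 500), min_size=2, max_size=8),
        target=st.floats(0, 1, allow_nan=False),
    )
    def test_conserves_total_and_never_lowers_virtual(self, profiles, counts, target):
        cities = ["Vancouver", "Victoria", "Kelowna", "Cranbrook"]
        rows = [
            (
                cities[i % len(cities)],
                QUARTERS[i % 4],
                "in-person" if i % 3 else "virtual",
                c,
            )
            for i, c in enumerate(counts)
        ]
        v = (
            visits_frame(rows)
            .groupby(["city", "fiscal_quarter", "modality"], as_index=False)["count"]
            .sum()
        )
        out = vc.apply_virtual_share(v, target, profiles)
        assert out["count"].sum() == v["count"].sum()

        def regional_virtual(df):
            df = df.assign(
                region=[profiles[c].region for c in df["city"]],
                is_virtual=df["modality"] == "virtual",
            )
            return df[df["is_virtual"]].groupby("region")["count"].sum()

        before, after = regional_virtual(v), regional_virtual(out)
        for region in before.index:
            assert after.get(region, 0) >= before[region]

    def test_table6_reaches_40_percent_per_region(self, table6, profiles):
        out = vc.apply_virtual_share(table6, 0.40, profiles)
        out = out.assign(
            region=[
                profiles[c].region if c in profiles else "Unknown" for c in out["city"]
            ]
        )
        for region, grp in out.groupby("region"):
            frac = grp.loc[grp["modality"] == "virtual", "count"].sum() / grp["count"].sum()
            assert frac >= 0.40 - 1.0 / grp["count"].sum() - 1e-9


class TestScenarioTotal:
    def test_single_virtual_visit(self, profiles, factors, builtins):
        v = visits_frame([("Vancouver", "Q1", "virtual", 1)])
        report = vc.scenario_total(v, profiles, builtins["realistic"], factors)
        assert report.grand_total_t == pytest.approx(63.7e-6)

    def test_empty_table_zero(self, profiles, factors, builtins):
        v = visits_frame([])
        report = vc.scenario_total(v, profiles, builtins["realistic"], factors)
        assert report.grand_total_t == 0.0

    def test_missing_profile_lists_cities(self, profiles, factors, builtins):
        v = visits_frame([("Atlantis", "Q1", "in-person", 3)])
        with pytest.raises(InvalidInputError, match="Atlantis"):
            vc.scenario_total(v, profiles, builtins["realistic"], factors)

    def test_unidentified_in_person_visits_cost_nothing(self, profiles, factors, builtins):
        v = visits_frame([("unidentified", "Q3", "in-person", 100)])
        report = vc.scenario_total(v, profiles, builtins["realistic"], factors)
        assert report.grand_total_t == 0.0
        assert report.metadata["unknown_region_zero_travel"]

    def test_additive_over_partitions(self, table6, profiles, factors, builtins):
        sc = builtins["realistic"]
        half1, half2 = table6.iloc[::2], table6.iloc[1::2]
        whole = vc.scenario_total(table6, profiles, sc, factors).grand_total_t
        parts = (
            vc.scenario_total(half1, profiles, sc, factors).grand_total_t
            + vc.scenario_total(half2, profiles, sc, factors).grand_total_t
        )
        assert whole == pytest.approx(parts, rel=1e-12)

    def test_matches_per_record_enumeration(self, profiles, factors, builtins):
        """10-row random table vs a brute-force per-record oracle."""
        rng = np.random.default_rng(42)
        cities = [c for c in profiles if c != "unidentified"]
        rows = [
            (
                rng.choice(cities),
                rng.choice(QUARTERS),
                rng.choice(["in-person", "virtual"]),
                int(rng.integers(1, 50)),
            )
            for _ in range(10)
        ]
        v = (
            visits_frame(rows)
            .groupby(["city", "fiscal_quarter", "modality"], as_index=False)["count"]
            .sum()
        )
        sc = builtins["realistic"]
        expected = 0.0
        for row in v.itertuples(index=False):
            if row.modality == "virtual":
                expected += row.count * vc.virtual_emission(factors)
            else:
                expected += row.count * vc.expected_visit_emission(
                    profiles[row.city], vc.season_for_quarter(row.fiscal_quarter), sc, factors
                )
        got = vc.scenario_total(v, profiles, sc, factors)
        assert got.grand_total_t == pytest.approx(expected, rel=1e-12)


class TestCompare:
    def test_equal_reports_zero_change(self, table6, profiles, factors, builtins):
        rep = vc.scenario_total(table6, profiles, builtins["realistic"], factors)
        assert vc.compare_scenarios(rep, rep) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "base, alt, expected", [(10_000, 8_600, -14.0), (10_000, 11_400, 14.0)]
    )
    def test_percent_change_arithmetic(self, base, alt, expected):
        def fake(total):
            rows = pd.DataFrame(
                [{"region": "X", "in_person_t": total, "virtual_t": 0.0, "total_t": total}]
            )
            return vc.EmissionReport(scenario="x", rows=rows)

        assert vc.compare_scenarios(fake(base), fake(alt)) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        empty = vc.EmissionReport(
            scenario="x",
            rows=pd.DataFrame(columns=["region", "in_person_t", "virtual_t", "total_t"]),
        )
        with pytest.raises(InvalidInputError):
            vc.compare_scenarios(empty, empty)
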