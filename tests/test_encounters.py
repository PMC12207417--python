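"""Encounter rates, geometry, activity filtering, colony exposure."""

import numpy as np
import pandas as pd
import pytest

from divetrace.encounters import (
    GridSpec,
    classify_activity_by_speed,
    coverage_by_hour,
    distance_to_nearest_colony,
    filter_to_fishing,
    haversine_km,
    median_intervessel_distance,
    penguin_consumption_equivalent,
    rate_grid,
    rate_timeseries,
    vrz_exposure,
)
from divetrace.simulate import make_colony_set, simulate_vessel_track

from conftest import make_events


def law_of_cosines_km(lat1, lon1, lat2, lon2, R=6371.0):
    """Independent spherical-law-of-cosines oracle."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    return R * np.arccos(
        np.clip(np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl), -1, 1)
    )


class TestGeometry:
    def test_haversine_matches_law_of_cosines_within_1m(self):
        rng = np.random.default_rng(0)
        lat1 = rng.uniform(-65, -50, 50)
        lon1 = rng.uniform(-60, -30, 50)
        lat2 = lat1 + rng.uniform(-2, 2, 50)
        lon2 = lon1 + rng.uniform(-2, 2, 50)
        d1 = haversine_km(lat1, lon1, lat2, lon2)
        d2 = law_of_cosines_km(lat1, lon1, lat2, lon2)
        assert np.max(np.abs(d1 - d2)) < 1e-3     # < 1 m

    def test_one_degree_latitude(self):
        d = haversine_km(-60.0, -45.0, -61.0, -45.0)
        assert d == pytest.approx(np.pi * 6371.0 / 180.0, abs=1e-6)
        assert d == pytest.approx(111.19, abs=0.01)

    def test_coincident_points_zero(self):
        assert haversine_km(-60.0, -45.0, -60.0, -45.0) == 0.0

    def test_nearest_colony_equals_brute_force_minimum(self):
        colonies = make_colony_set(3, populations=[1e5] * 3, seed=2)
        pos = pd.DataFrame({"lat": [-60.3, -60.8], "lon": [-45.1, -46.2]})
        out = distance_to_nearest_colony(pos, colonies)
        for i, p in pos.iterrows():
            dists = [
                float(haversine_km(p.lat, p.lon, c.lat, c.lon))
                for c in colonies.itertuples()
            ]
            assert out.loc[i, "distance_km"] == pytest.approx(min(dists))

    def test_colony_at_position_is_zero_km(self):
        colonies = make_colony_set(2, seed=0)
        pos = colonies[["lat", "lon"]].iloc[[0]]
        out = distance_to_nearest_colony(pos, colonies)
        assert out["distance_km"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_empty_colony_set_rejected(self):
        with pytest.raises(ValueError):
            distance_to_nearest_colony(
                pd.DataFrame({"lat": [0.0], "lon": [0.0]}), make_colony_set(0)
            )


class TestActivityClassification:
    @pytest.mark.parametrize(
        "speed,status",
        [(0.2, "stationary"), (0.3, "fishing"), (3.0, "fishing"),
         (5.0, "fishing"), (5.01, "steaming")],
    )
    def test_speed_window_bounds(self, speed, status):
        track = pd.DataFrame(
            {"timestamp": [pd.Timestamp("2022-01-01")], "lat": [0.0],
             "lon": [0.0], "speed_kn": [speed]}
        )
        assert classify_activity_by_speed(track)["status"].iloc[0] == status

    def test_supplied_status_takes_precedence(self):
        track = pd.DataFrame(
            {"timestamp": pd.to_datetime(["2022-01-01", "2022-01-02"]),
             "lat": [0.0, 0.0], "lon": [0.0, 0.0], "speed_kn": [3.0, 3.0],
             "status": ["steaming", None]}
        )
        out = classify_activity_by_speed(track)
        assert list(out["status"]) == ["steaming", "fishing"]

    def test_negative_speed_rejected(self):
        track = pd.DataFrame(
            {"timestamp": [pd.Timestamp("2022-01-01")], "lat": [0.0],
             "lon": [0.0], "speed_kn": [-0.1]}
        )
        with pytest.raises(ValueError):
            classify_activity_by_speed(track)


class TestFishingFilter:
    def half_steaming_setup(self):
        t0 = pd.Timestamp("2022-01-01")
        track = pd.DataFrame(
            {
                "timestamp": [t0, t0 + pd.Timedelta(hours=1), t0 + pd.Timedelta(hours=2)],
                "lat": [-60.0] * 3, "lon": [-45.0] * 3,
                "speed_kn": [3.0, 8.0, 8.0],
            }
        )
        ledger = pd.DataFrame(
            {
                "vessel_id": ["V1", "V1"],
                "t_start": [t0, t0 + pd.Timedelta(hours=1)],
                "t_end": [t0 + pd.Timedelta(hours=1), t0 + pd.Timedelta(hours=2)],
                "hours": [1.0, 1.0],
                "lat": [-60.0, -60.0], "lon": [-45.0, -45.0],
            }
        )
        events = make_events(
            [(t0 + pd.Timedelta(minutes=10), "bubble_trail", 3.0, -60.0, -45.0)]
        )
        return events, ledger, track

    def test_all_fishing_track_is_identity(self):
        events, ledger, track = self.half_steaming_setup()
        track["speed_kn"] = 3.0
        ev, ld = filter_to_fishing(events, ledger, track)
        assert len(ev) == len(events)
        assert ld["hours"].sum() == pytest.approx(2.0)

    def test_steaming_half_doubles_the_rate(self):
        """Half the hours steam away with all events in the fishing half:
        hours halve, events stay, the rate doubles."""
        events, ledger, track = self.half_steaming_setup()
        rate_before = events["duration_min"].sum() / ledger["hours"].sum()
        ev, ld = filter_to_fishing(events, ledger, track)
        assert ld["hours"].sum() == pytest.approx(1.0)
        assert len(ev) == 1
        rate_after = ev["duration_min"].sum() / ld["hours"].sum()
        assert rate_after == pytest.approx(2 * rate_before)

    def test_event_at_transition_assigned_by_start_timestamp(self):
        events, ledger, track = self.half_steaming_setup()
        t_edge = pd.Timestamp("2022-01-01") + pd.Timedelta(hours=1)
        events = make_events([(t_edge, "bubble_trail", 1.0, -60.0, -45.0)])
        ev, _ = filter_to_fishing(events, ledger, track)
        assert len(ev) == 0       # start falls in the steaming period


class TestRates:
    def test_thirty_minutes_in_ten_hours_is_three_per_hour(self, simple_ledger):
        simple_ledger["hours"] = [5.0, 5.0]
        events = make_events(
            [("2022-01-01 00:05", "bubble_trail", 30.0, -60.5, -45.5)]
        )
        out = rate_timeseries(events, simple_ledger, bin="7D")
        assert out["bubble_trail_rate_min_per_h"].iloc[0] == pytest.approx(3.0)

    def test_zero_events_give_zero_rate_and_zero_log_rate(self, simple_ledger):
        out = rate_timeseries(make_events([]), simple_ledger, bin="7D")
        assert out["bubble_trail_rate_min_per_h"].iloc[0] == 0.0
        assert out["bubble_trail_log_rate"].iloc[0] == 0.0   # log10(0 + 1)

    def test_log_rate_uses_rate_plus_one(self, simple_ledger):
        events = make_events(
            [("2022-01-01 00:05", "whale", 9.0, -60.5, -45.5)]
        )
        out = rate_timeseries(events, simple_ledger, bin="7D")
        assert out["whale_log_rate"].iloc[0] == pytest.approx(np.log10(9.0 + 1.0))

    def test_rebinning_conserves_rate(self):
        """Aggregating minutes and hours before dividing equals the
        hour-weighted mean of sub-bin rates."""
        t0 = pd.Timestamp("2022-01-03")
        ledger = pd.DataFrame(
            {
                "vessel_id": ["V1"] * 4,
                "t_start": [t0 + pd.Timedelta(days=d) for d in range(4)],
                "t_end": [t0 + pd.Timedelta(days=d, hours=6) for d in range(4)],
                "hours": [6.0, 2.0, 4.0, 8.0],
                "lat": [-60.0] * 4, "lon": [-45.0] * 4,
            }
        )
        events = make_events(
            [
                (t0 + pd.Timedelta(days=0, hours=1), "whale", 12.0, -60.0, -45.0),
                (t0 + pd.Timedelta(days=1, hours=2), "whale", 6.0, -60.0, -45.0),
                (t0 + pd.Timedelta(days=3, hours=3), "whale", 10.0, -60.0, -45.0),
            ]
        )
        daily = rate_timeseries(events, ledger, bin="1D")
        weekly = rate_timeseries(events, ledger, bin="7D")
        agg = (
            daily["whale_min"].sum() / daily["observation_hours"].sum()
        )
        assert weekly["whale_rate_min_per_h"].iloc[0] == pytest.approx(agg, rel=1e-12)
        weighted = (
            (daily["whale_rate_min_per_h"] * daily["observation_hours"]).sum()
            / daily["observation_hours"].sum()
        )
        assert agg == pytest.approx(weighted, rel=1e-12)

    def test_bin_totals_conserve_event_table(self, simple_ledger):
        events = make_events(
            [
                ("2022-01-01 00:05", "whale", 2.0, -60.5, -45.5),
                ("2022-01-01 01:05", "bubble_trail", 1.5, -60.5, -45.4),
            ]
        )
        out = rate_timeseries(events, simple_ledger, bin="1D")
        assert out["whale_min"].sum() == pytest.approx(2.0)
        assert out["bubble_trail_min"].sum() == pytest.approx(1.5)
        assert out["observation_hours"].sum() == pytest.approx(1.0)


class TestRateGrid:
    def test_single_cell_matches_timeseries_total(self, simple_ledger):
        events = make_events(
            [("2022-01-01 00:05", "bubble_trail", 4.0, -60.5, -45.45)]
        )
        grid = GridSpec(1.0, 1.0)
        out = rate_grid(events, simple_ledger, grid)
        assert len(out) == 1
        assert out["observation_hours"].iloc[0] == pytest.approx(1.0)
        assert out["bubble_trail_min"].iloc[0] == pytest.approx(4.0)

    def test_cell_edges_half_open(self):
        grid = GridSpec(0.5, 0.5)
        i, j = grid.cell_index(np.array([0.5]), np.array([1.0]))
        assert (i[0], j[0]) == (2, 1)   # exactly on the edge -> upper cell

    def test_two_cells_with_2to1_minutes_have_2to1_rates(self):
        t0 = pd.Timestamp("2022-01-01")
        ledger = pd.DataFrame(
            {
                "vessel_id": ["V1", "V1"],
                "t_start": [t0, t0 + pd.Timedelta(hours=1)],
                "t_end": [t0 + pd.Timedelta(hours=1), t0 + pd.Timedelta(hours=2)],
                "hours": [1.0, 1.0],
                "lat": [-60.25, -60.75], "lon": [-45.25, -45.75],
            }
        )
        events = make_events(
            [
                (t0, "whale", 4.0, -60.25, -45.25),
                (t0 + pd.Timedelta(hours=1), "whale", 2.0, -60.75, -45.75),
            ]
        )
        out = rate_grid(events, ledger, GridSpec(0.5, 0.5)).sort_values("whale_min")
        rates = out["whale_rate_min_per_h"].to_numpy()
        assert rates[1] == pytest.approx(2 * rates[0])

    def test_observed_cells_without_events_included(self, simple_ledger):
        out = rate_grid(make_events([]), simple_ledger, GridSpec(0.05, 0.05))
        assert len(out) == 2
        assert (out["whale_rate_min_per_h"] == 0.0).all()

    def test_grid_conserves_minutes_and_hours(self, simple_ledger):
        events = make_events(
            [
                ("2022-01-01 00:05", "whale", 2.0, -60.5, -45.49),
                ("2022-01-01 01:10", "bubble_trail", 3.0, -60.5, -45.38),
            ]
        )
        out = rate_grid(events, simple_ledger, GridSpec(0.05, 0.05))
        assert out["whale_min"].sum() == pytest.approx(2.0)
        assert out["bubble_trail_min"].sum() == pytest.approx(3.0)
        assert out["observation_hours"].sum() == pytest.approx(1.0)


class TestVRZ:
    def setup_exposure(self, event_km, colony_lat=-60.5, colony_lon=-45.5):
        colonies = pd.DataFrame(
            {"colony_id": ["C1"], "lat": [colony_lat], "lon": [colony_lon],
             "population": [1e6], "taxon": ["penguin"]}
        )
        dlat = event_km / 111.19493
        events = make_events(
            [("2022-01-01 00:05", "bubble_trail", 2.0,
              colony_lat + dlat, colony_lon)]
        )
        ledger = pd.DataFrame(
            {
                "vessel_id": ["V1"],
                "t_start": [pd.Timestamp("2022-01-01")],
                "t_end": [pd.Timestamp("2022-01-01 01:00")],
                "hours": [1.0],
                "lat": [colony_lat + dlat], "lon": [colony_lon],
            }
        )
        return events, ledger, colonies

    def test_29km_event_inside_buffer(self):
        events, ledger, colonies = self.setup_exposure(29.0)
        rep = vrz_exposure(events, ledger, colonies)
        assert rep["events"]["inside_buffer"].iloc[0]

    def test_31km_event_outside_buffer(self):
        events, ledger, colonies = self.setup_exposure(31.0)
        rep = vrz_exposure(events, ledger, colonies)
        assert not rep["events"]["inside_buffer"].iloc[0]

    def test_all_events_at_10km_give_full_within15_share(self):
        events, ledger, colonies = self.setup_exposure(10.0)
        rep = vrz_exposure(events, ledger, colonies)
        assert rep["within_15km_share"] == pytest.approx(1.0)

    def test_cutoff_stratification(self):
        events, ledger, colonies = self.setup_exposure(10.0)
        rep = vrz_exposure(events, ledger, colonies, cutoff="2018-07-01")
        assert rep["events"]["period"].iloc[0] == "after"
        rep2 = vrz_exposure(events, ledger, colonies, cutoff="2023-01-01")
        assert rep2["events"]["period"].iloc[0] == "before"
        assert rep2["strata"]["before_inside"]["bubble_trail_rate_min_per_h"] == pytest.approx(2.0)


class TestConsumption:
    def test_one_million_penguins_need_100k_tonnes(self):
        assert penguin_consumption_equivalent(1_000_000) == pytest.approx(100_000.0)

    def test_zero_penguins(self):
        assert penguin_consumption_equivalent(0) == 0.0

    def test_regional_population(self):
        assert penguin_consumption_equivalent(2_800_000) == pytest.approx(280_000.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            penguin_consumption_equivalent(-1)


class TestFleetDiagnostics:
    def test_identical_tracks_zero_distance(self):
        t = simulate_vessel_track([(7200, 3.0, 45.0)], start=(-60.0, -45.0))
        out = median_intervessel_distance([t, t.copy()], bin="1h")
        assert np.allclose(out["median_distance_km"], 0.0)

    def test_parallel_tracks_offset_point1_degree(self):
        a = simulate_vessel_track([(7200, 3.0, 90.0)], start=(-60.0, -45.0))
        b = simulate_vessel_track([(7200, 3.0, 90.0)], start=(-60.1, -45.0))
        out = median_intervessel_distance([a, b], bin="1h")
        assert np.allclose(out["median_distance_km"], 11.12, atol=0.02)

    def test_three_vessels_median_equals_brute_force(self):
        tracks = [
            simulate_vessel_track([(3600, 3.0, h)], start=(-60.0 - 0.05 * i, -45.0))
            for i, h in enumerate([0.0, 90.0, 180.0])
        ]
        out = median_intervessel_distance(tracks, bin="1h", match_interval="30min")
        ts = tracks[0]["timestamp"].iloc[30]   # a matched timestamp
        ps = [
            (tr.loc[tr.timestamp == ts, "lat"].iloc[0],
             tr.loc[tr.timestamp == ts, "lon"].iloc[0])
            for tr in tracks
        ]
        dists = [
            float(haversine_km(*ps[i], *ps[j]))
            for i, j in [(0, 1), (0, 2), (1, 2)]
        ]
        # the 30-min matched grid includes this instant; compare medians
        row = out[out.timestamp <= ts].iloc[-1]
        assert row["median_distance_km"] == pytest.approx(np.median(dists), rel=0.1)

    def test_single_vessel_rejected(self):
        t = simulate_vessel_track([(3600, 3.0, 0.0)], start=(-60.0, -45.0))
        with pytest.raises(ValueError):
            median_intervessel_distance([t])


class TestCoverage:
    def test_uniform_ledger_gives_equal_bins(self):
        t0 = pd.Timestamp("2022-01-01")
        ledger = pd.DataFrame(
            {
                "t_start": [t0 + pd.Timedelta(hours=h) for h in range(48)],
                "hours": [0.5] * 48,
            }
        )
        out = coverage_by_hour(ledger)
        assert np.allclose(out["observation_hours"], 1.0)

    def test_night_only_ledger_leaves_day_bins_empty(self):
        t0 = pd.Timestamp("2022-01-01 02:00")
        ledger = pd.DataFrame({"t_start": [t0], "hours": [2.0]})
        out = coverage_by_hour(ledger)
        assert out.loc[out.hour == 2, "observation_hours"].iloc[0] == 2.0
        assert out.loc[out.hour == 12, "observation_hours"].iloc[0] == 0.0

    def test_bin_sum_equals_ledger_total(self):
        rng = np.random.default_rng(0)
        t0 = pd.Timestamp("2022-01-01")
        ledger = pd.DataFrame(
            {
                "t_start": [t0 + pd.Timedelta(hours=float(h)) for h in rng.uniform(0, 100, 30)],
                "hours": rng.uniform(0, 1, 30),
            }
        )
        out = coverage_by_hour(ledger)
        assert out["observation_hours"].sum() == pytest.approx(ledger["hours"].sum())
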