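"""Location and mode assignment: virtual zones, gravity, OD, coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mobisynth.config import LocationConfig
from mobisynth.errors import DataError, FitError
from mobisynth import fixtures, location_mode as lm


class TestVirtualZones:
    def test_single_cell_zone_weight_one(self):
        zones = pd.DataFrame({"zone_id": ["Z"]})
        grid = pd.DataFrame({"cell_id": ["C"], "zone_id": ["Z"], "x_min": [0.0],
                             "y_min": [0.0], "size": [1000.0], "population": [400]})
        vz = lm.build_virtual_zones(zones, grid)
        assert len(vz) == 1 and vz["population_weight"].iloc[0] == 1.0

    def test_weights_proportional_to_cell_population(self):
        zones = pd.DataFrame({"zone_id": ["Z"]})
        grid = pd.DataFrame({"cell_id": ["C1", "C2"], "zone_id": ["Z", "Z"],
                             "x_min": [0.0, 1000.0], "y_min": [0.0, 0.0],
                             "size": [1000.0, 1000.0], "population": [300, 100]})
        vz = lm.build_virtual_zones(zones, grid).set_index("cell_id")
        assert vz.at["C1", "population_weight"] == pytest.approx(0.75)
        assert vz.at["C2", "population_weight"] == pytest.approx(0.25)

    def test_weights_sum_to_one_per_zone(self, small_world):
        vz = lm.build_virtual_zones(small_world.zones, small_world.grid)
        sums = vz.groupby("zone_id")["population_weight"].sum()
        np.testing.assert_allclose(sums, 1.0)


class TestHomeBuildings:
    def test_degenerate_size_model(self, small_world, rng):
        vz = lm.build_virtual_zones(small_world.zones, small_world.grid)
        hh = pd.DataFrame({"HId": range(1, 101),
                           "zone_id": small_world.zones["zone_id"].iloc[0],
                           "size": [1] * 50 + [5] * 50})
        cfg = LocationConfig(detached_intercept=-200.0, detached_slope=50.0)
        homes = lm.assign_home_buildings(hh, vz, small_world.buildings, cfg, rng)
        usage = small_world.buildings.set_index("building_id")["usage_type"]
        types = homes.map(usage)
        assert (types.loc[1:50] == "apartment").all()
        assert (types.loc[51:100] == "detached_house").all()

    def test_detached_share_monotone_in_size(self, small_world, rng):
        vz = lm.build_virtual_zones(small_world.zones, small_world.grid)
        usage = small_world.buildings.set_index("building_id")["usage_type"]
        shares = []
        for size in (1, 2, 4, 6):
            hh = pd.DataFrame({"HId": range(1, 2001),
                               "zone_id": small_world.zones["zone_id"].iloc[0],
                               "size": size})
            homes = lm.assign_home_buildings(hh, vz, small_world.buildings,
                                             LocationConfig(), rng)
            shares.append((homes.map(usage) == "detached_house").mean())
        assert all(a <= b + 0.03 for a, b in zip(shares, shares[1:]))

    def test_homes_are_residential(self, midscale_result):
        usage = midscale_result.world.buildings.set_index("building_id")["usage_type"]
        types = midscale_result.home_buildings.map(usage)
        assert types.isin(["detached_house", "apartment"]).all()


class TestGravityFit:
    @pytest.mark.parametrize("purpose,mode", [("W", "Car"), ("S", "Walking"),
                                              ("O", "PublicTransport")])
    def test_recovers_true_beta(self, small_world, purpose, mode):
        params = small_world.behaviour
        truth = params.gravity_beta[f"{purpose},{mode}"]
        d = small_world.distance_matrix_km()
        trips = fixtures.generate_trips(small_world, params, 2000, seed=5,
                                        purposes=(purpose,), modes=(mode,))
        masses = {purpose: small_world.zone_attraction_mass(purpose)}
        fit = lm.fit_gravity(trips, small_world.zones, masses, d)
        assert fit.beta[(purpose, mode)] == pytest.approx(truth, rel=0.15)

    def test_large_beta_limit_concentrates_on_nearest(self, small_world):
        d = small_world.distance_matrix_km()
        mass = small_world.zone_attraction_mass("W")
        probs = fixtures.gravity_probabilities(d, mass, 50.0)
        origin = d.index[0]
        # nearest zone is the origin itself (distance 0)
        assert probs.loc[origin, origin] > 0.999

    def test_symmetric_two_zone_geometry(self):
        d = pd.DataFrame([[0.0, 2.0], [2.0, 0.0]], index=["A", "B"],
                         columns=["A", "B"])
        mass = pd.Series([1.0, 1.0], index=["A", "B"])
        probs = fixtures.gravity_probabilities(d, mass, 0.3)
        assert probs.loc["A", "B"] == pytest.approx(probs.loc["B", "A"])

    def test_too_few_trips_rejected(self, small_world):
        trips = fixtures.generate_trips(small_world, small_world.behaviour, 5,
                                        seed=0, purposes=("W",), modes=("Car",))
        with pytest.raises(DataError, match="trips"):
            lm.fit_gravity(trips, small_world.zones,
                           {"W": small_world.zone_attraction_mass("W")},
                           small_world.distance_matrix_km())

    def test_unreachable_mean_distance_raises_fit_error(self, small_world):
        d = small_world.distance_matrix_km()
        trips = fixtures.generate_trips(small_world, small_world.behaviour, 100,
                                        seed=0, purposes=("W",), modes=("Car",))
        trips["distance_km"] = d.to_numpy().max() * 2  # beyond any model mean
        with pytest.raises(FitError, match="bracketable"):
            lm.fit_gravity(trips, small_world.zones,
                           {"W": small_world.zone_attraction_mass("W")}, d)


class TestODProbabilities:
    def test_flows_normalised(self):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["A", "B"],
                         columns=["A", "B"])
        od = pd.DataFrame({"origin": ["A", "A"], "destination": ["A", "B"],
                           "mode": "Car", "purpose": "work", "flow": [10.0, 30.0]})
        probs = lm.build_od_probabilities(None, d, od=od)
        np.testing.assert_allclose(probs.get("A", "W", "Car"), [0.25, 0.75])

    def test_row_sums_equal_one(self, small_world):
        d = small_world.distance_matrix_km()
        probs = lm.build_od_probabilities(small_world.zones, d, od=small_world.od)
        for vec in probs.probs.values():
            assert vec.sum() == pytest.approx(1.0)

    def test_supplied_od_takes_precedence_over_gravity(self, small_world):
        d = small_world.distance_matrix_km()
        mass = small_world.zone_attraction_mass("W")
        gravity = lm.GravityFit(beta={("W", "Car"): 5.0}, masses={"W": mass},
                                residual={("W", "Car"): 0.0})
        od_only = lm.build_od_probabilities(small_world.zones, d, od=small_world.od)
        both = lm.build_od_probabilities(small_world.zones, d, od=small_world.od,
                                         gravity=gravity)
        origin = d.index[0]
        np.testing.assert_array_equal(both.get(origin, "W", "Car"),
                                      od_only.get(origin, "W", "Car"))

    def test_school_comes_from_gravity(self, small_world):
        d = small_world.distance_matrix_km()
        mass = small_world.zone_attraction_mass("S")
        gravity = lm.GravityFit(beta={("S", "Walking"): 0.5}, masses={"S": mass},
                                residual={("S", "Walking"): 0.0})
        probs = lm.build_od_probabilities(small_world.zones, d, od=small_world.od,
                                          gravity=gravity)
        expected = fixtures.gravity_probabilities(d, mass, 0.5)
        np.testing.assert_allclose(probs.get(d.index[0], "S", "Walking"),
                                   expected.iloc[0].to_numpy())

    def test_all_zero_row_rejected(self):
        d = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["A", "B"],
                         columns=["A", "B"])
        od = pd.DataFrame({"origin": ["A"], "destination": ["B"], "mode": ["Car"],
                           "purpose": ["work"], "flow": [0.0]})
        with pytest.raises(DataError, match="all-zero"):
            lm.build_od_probabilities(None, d, od=od)


class TestModeAndDestinationAssignment:
    def test_carless_households_never_drive(self, midscale_result):
        res = midscale_result
        hh_cars = res.households.set_index("HId")["n_cars"]
        persons = res.persons.set_index("PId")
        for s in res.schedules:
            if s.n_trips and res.tour_modes[s.pid] == "Car":
                assert hh_cars[persons.at[s.pid, "HId"]] >= 1

    def test_realized_mode_shares_track_model(self, midscale_result):
        # multinomial bound on tour-mode shares vs the model's mean probabilities
        res = midscale_result
        from mobisynth.location_mode import train_mode_model
        model = train_mode_model(res.world.survey_persons, res.world.survey_diary)
        with_trips = [s.pid for s in res.schedules if s.n_trips > 0]
        sub = res.persons.set_index("PId").loc[with_trips].copy()
        hh_cars = res.households.set_index("HId")["n_cars"]
        carless = (sub["HId"].map(hh_cars) == 0).to_numpy()
        sub["has_car"] = (~carless).astype(int)
        P = model.predict(sub.reset_index())
        car_col = model.choice_set.index("Car")
        no_drive = carless | (sub["age"].to_numpy() < 18)
        P[no_drive, car_col] = 0
        P = P / P.sum(axis=1, keepdims=True)
        n = len(sub)
        realized = res.tour_modes.value_counts()
        for k, mode in enumerate(model.choice_set):
            expect = P[:, k].sum()
            se = np.sqrt((P[:, k] * (1 - P[:, k])).sum())
            assert abs(realized.get(mode, 0) - expect) < 4 * se + 2

    def test_travel_time_distance_rank_coupling(self, midscale_result):
        """Longer travel times get farther destination zones (Spearman > 0.9
        within each origin/purpose/mode stratum)."""
        res = midscale_result
        d = res.world.distance_matrix_km()
        at = res.activity_table
        rows = []
        for s in res.schedules:
            if s.n_trips == 0:
                continue
            g = at[at.PId == s.pid].sort_values("activity_id")
            gap = s.travel_total / s.n_trips
            zs, ps = g["zone_id"].to_numpy(), g["purpose"].to_numpy()
            for i in range(1, len(g)):
                if ps[i] == "Home":
                    continue
                rows.append({"origin": zs[i - 1], "purpose": ps[i],
                             "mode": res.tour_modes[s.pid], "tt": gap,
                             "dist": d.loc[zs[i - 1], zs[i]]})
        df = pd.DataFrame(rows)
        checked = 0
        for _, g in df.groupby(["origin", "purpose", "mode"]):
            if len(g) >= 30 and g["tt"].nunique() > 3 and g["dist"].nunique() > 1:
                rho = spearmanr(g["tt"], g["dist"]).statistic
                assert rho > 0.9
                checked += 1
        assert checked >= 20

    def test_home_episodes_share_one_building(self, midscale_result):
        at = midscale_result.activity_table
        homes = at[at["purpose"] == "Home"]
        assert (homes.groupby("PId")["building_id"].nunique() == 1).all()

    def test_every_activity_located(self, midscale_result):
        at = midscale_result.activity_table
        assert at["building_id"].notna().all()
        assert (at["zone_id"] != "").all()
        buildings = midscale_result.world.buildings.set_index("building_id")
        sample = at.sample(500, random_state=0)
        assert (sample["zone_id"].to_numpy()
                == buildings.loc[sample["building_id"], "zone_id"].to_numpy()).all()
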