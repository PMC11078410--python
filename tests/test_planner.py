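"""Pilot-survey geometry and the myopic waypoint utility maximiser."""

import numpy as np
import pytest

from bloommap import (
    FleetState,
    LGPHyperparams,
    LocalPosition,
    LogGPModel,
    PlannerConfig,
    candidate_waypoints,
    choose_waypoint,
    pilot_path,
    pilot_x,
    utility,
)


class TestPilotX:
    @pytest.mark.parametrize(
        "n_v,N_v,V_x,expected",
        [(0, 1, 1500.0, 750.0), (0, 2, 1500.0, 375.0), (1, 2, 1500.0, 1125.0)],
    )
    def test_hand_evaluated_positions(self, n_v, N_v, V_x, expected):
        assert pilot_x(n_v, N_v, V_x) == pytest.approx(expected)

    def test_positions_symmetric_about_midline(self):
        for N_v in (1, 2, 3, 4, 7):
            xs = [pilot_x(i, N_v, 1500.0) for i in range(N_v)]
            np.testing.assert_allclose(xs, [1500.0 - x for x in reversed(xs)])
            assert all(0 < x < 1500 for x in xs)

    def test_index_out_of_fleet_raises(self):
        with pytest.raises(ValueError):
            pilot_x(2, 2, 1500.0)


class TestPilotPath:
    def test_crosses_from_y_zero_to_y_max(self, field_volume):
        wps = pilot_path(field_volume, PlannerConfig(), 0, 2)
        assert wps[0].y == 0.0
        assert wps[-1].y == pytest.approx(field_volume.extent[1])
        ys = [w.y for w in wps]
        assert np.all(np.diff(ys) > 0)

    def test_two_vehicle_paths_mirror_about_midline(self, field_volume):
        a = pilot_path(field_volume, PlannerConfig(), 0, 2)
        b = pilot_path(field_volume, PlannerConfig(), 1, 2)
        for wa, wb in zip(a, b):
            assert wa.x == pytest.approx(field_volume.extent[0] - wb.x)
            assert (wa.y, wa.z) == (wb.y, wb.z)

    def test_undulates_between_surface_and_max_depth(self, field_volume):
        wps = pilot_path(field_volume, PlannerConfig(), 0, 1)
        zs = [w.z for w in wps]
        assert all(0 <= z <= field_volume.extent[2] for z in zs)
        assert max(zs) == pytest.approx(field_volume.extent[2])
        assert min(zs) == 0.0
        # sawtooth: strict alternation between the extremes
        assert all(z in (0.0, field_volume.extent[2]) for z in zs)
        assert all(za != zb for za, zb in zip(zs, zs[1:]))


def brute_force_candidates(x_v, plan, cfg):
    """All 3 n_theta raw candidates with an explicit in-volume test."""
    r = plan.effective_radius(cfg)
    z_d = plan.effective_z_step(cfg)
    out = []
    for dz in (-z_d, 0.0, z_d):
        for i in range(plan.n_theta):
            th = 2 * np.pi * i / plan.n_theta
            c = LocalPosition(x_v.x + r * np.cos(th), x_v.y + r * np.sin(th), x_v.z + dz)
            vx, vy, vz = cfg.extent
            if 0 <= c.x <= vx and 0 <= c.y <= vy and 0 <= c.z <= vz:
                out.append(c)
    return out


class TestCandidateWaypoints:
    def test_interior_position_yields_24(self, field_volume):
        cands = candidate_waypoints(
            LocalPosition(750, 750, 25), PlannerConfig(n_theta=8), field_volume
        )
        assert len(cands) == 24

    def test_surface_position_screens_up_layer(self, field_volume):
        # at z = 0 the dz = -z_d layer leaves the volume: 16 candidates remain
        cands = candidate_waypoints(
            LocalPosition(750, 750, 0), PlannerConfig(n_theta=8), field_volume
        )
        assert len(cands) == 16

    def test_wall_screening_matches_brute_force(self, field_volume, rng):
        plan = PlannerConfig(n_theta=8)
        # near-surface, near-wall position: fewer than 16 remain
        p = LocalPosition(50, 750, 0)
        got = candidate_waypoints(p, plan, field_volume)
        want = brute_force_candidates(p, plan, field_volume)
        assert len(got) == len(want) < 16
        # random positions incl. corners agree with the brute-force oracle
        for _ in range(50):
            p = LocalPosition(*rng.uniform((0, 0, 0), field_volume.extent))
            got = candidate_waypoints(p, plan, field_volume)
            want = brute_force_candidates(p, plan, field_volume)
            assert [(c.x, c.y, c.z) for c in got] == [(c.x, c.y, c.z) for c in want]

    def test_all_candidates_inside_volume(self, field_volume, rng):
        plan = PlannerConfig(n_theta=8)
        for _ in range(30):
            p = LocalPosition(*rng.uniform((0, 0, 0), field_volume.extent))
            for c in candidate_waypoints(p, plan, field_volume):
                assert c.in_volume(field_volume)

    def test_outside_vehicle_position_rejected(self, field_volume):
        with pytest.raises(ValueError):
            candidate_waypoints(LocalPosition(-10, 0, 0), PlannerConfig(), field_volume)


class TestUtility:
    def test_greedy_on_mean(self):
        plan = PlannerConfig(k_mu=1, k_sigma=0, k_l=0)
        fleet = FleetState(own_id=0)
        u1 = utility(LocalPosition(0, 0, 0), 2.0, 9.0, fleet, plan)
        u2 = utility(LocalPosition(0, 0, 0), 1.0, 99.0, fleet, plan)
        assert u1 > u2

    def test_pure_exploration_on_variance(self):
        plan = PlannerConfig(k_mu=0, k_sigma=1, k_l=0)
        fleet = FleetState(own_id=0)
        assert utility(LocalPosition(0, 0, 0), 99.0, 1.0, fleet, plan) < utility(
            LocalPosition(0, 0, 0), 0.1, 2.0, fleet, plan
        )

    def test_penalty_is_one_at_standoff_radius(self):
        plan = PlannerConfig(k_mu=1, k_sigma=0, k_l=300.0)
        fleet = FleetState(own_id=0)
        fleet.update(1, LocalPosition(300.0, 0, 0), 0.0)
        # (k_l / d)^2 = 1 exactly when the other vehicle is k_l away
        u = utility(LocalPosition(0, 0, 0), 5.0, 0.0, fleet, plan)
        assert u == pytest.approx(5.0 - 1.0)

    def test_horizontal_distance_only(self):
        plan = PlannerConfig(k_mu=1, k_sigma=0, k_l=300.0)
        fleet = FleetState(own_id=0)
        fleet.update(1, LocalPosition(300.0, 0, 45.0), 0.0)  # deep neighbour
        u = utility(LocalPosition(0, 0, 0), 5.0, 0.0, fleet, plan)
        assert u == pytest.approx(4.0)

    def test_colocated_vehicle_scores_minus_infinity(self):
        plan = PlannerConfig()
        fleet = FleetState(own_id=0)
        fleet.update(1, LocalPosition(10.0, 10.0, 30.0), 0.0)
        assert utility(LocalPosition(10, 10, 0), 100.0, 100.0, fleet, plan) == -np.inf

    def test_monotone_in_each_term(self):
        plan = PlannerConfig(k_mu=1, k_sigma=1, k_l=300)
        fleet = FleetState(own_id=0)
        fleet.update(1, LocalPosition(500, 0, 0), 0.0)
        base = utility(LocalPosition(0, 0, 0), 1.0, 1.0, fleet, plan)
        assert utility(LocalPosition(0, 0, 0), 2.0, 1.0, fleet, plan) > base
        assert utility(LocalPosition(0, 0, 0), 1.0, 2.0, fleet, plan) > base
        # moving the neighbour farther raises the score
        fleet.update(1, LocalPosition(900, 0, 0), 0.0)
        assert utility(LocalPosition(0, 0, 0), 1.0, 1.0, fleet, plan) > base

    def test_fleet_never_tracks_own_vehicle(self):
        fleet = FleetState(own_id=3)
        fleet.update(3, LocalPosition(1, 1, 1), 0.0)
        assert fleet.positions == {}


def _fitted_model(hp, rng, n=30, extent=1500.0):
    locs = rng.uniform(0, extent, (n, 3))
    locs[:, 2] = rng.uniform(0, 50, n)
    y = np.exp(rng.normal(0.3, 1.0, n))
    return LogGPModel(y, locs, rng.uniform(0, 1000, n), hp).fit()


class TestChooseWaypoint:
    def test_matches_exhaustive_scoring(self, field_volume, field_hp, rng):
        res = _fitted_model(field_hp, rng)
        plan = PlannerConfig(n_theta=8)
        fleet = FleetState(own_id=0)
        fleet.update(1, LocalPosition(1200, 1200, 0), 0.0)
        x_v = LocalPosition(700, 700, 25)
        wp, score = choose_waypoint(x_v, res, 1500.0, fleet, plan, field_volume)

        cands = candidate_waypoints(x_v, plan, field_volume)
        scores = []
        for c in cands:
            p = res.predict(np.array([[c.x, c.y, c.z]]), 1500.0)
            scores.append(
                utility(c, float(p.y_hat[0]), float(p.sigma_y2[0]), fleet, plan)
            )
        k = int(np.argmax(scores))
        assert (wp.x, wp.y, wp.z) == (cands[k].x, cands[k].y, cands[k].z)
        assert score == pytest.approx(max(scores))

    def test_ties_break_to_lowest_candidate_index(self, field_volume, field_hp, rng):
        # zero utility weights make every candidate score exactly 0.0;
        # the first generated candidate must win the exact tie
        model = _fitted_model(field_hp, rng)
        x_v = LocalPosition(750, 750, 25)
        plan = PlannerConfig(n_theta=8, k_mu=0.0, k_sigma=0.0, k_l=0.0)
        wp, score = choose_waypoint(
            x_v, model, 0.0, FleetState(own_id=0), plan, field_volume
        )
        assert score == 0.0
        first = candidate_waypoints(x_v, plan, field_volume)[0]
        assert (wp.x, wp.y, wp.z) == (first.x, first.y, first.z)

    def test_chosen_waypoint_always_inside_volume(self, field_volume, field_hp, rng):
        res = _fitted_model(field_hp, rng)
        plan = PlannerConfig(n_theta=8)
        fleet = FleetState(own_id=0)
        for _ in range(20):
            x_v = LocalPosition(*rng.uniform((0, 0, 0), field_volume.extent))
            wp, _ = choose_waypoint(x_v, res, 0.0, fleet, plan, field_volume)
            assert wp.in_volume(field_volume)

    def test_greedy_ascent_approaches_hotspot(self, field_volume, field_hp):
        # single distant data hotspot, k_sigma = 0: repeated choose->move steps
        # reduce the distance to the hotspot monotonically
        hot = np.array([1200.0, 1200.0, 25.0])
        locs = np.vstack([hot, [[200, 200, 25], [200, 1200, 25], [1200, 200, 25]]])
        y = np.array([50.0, 0.5, 0.5, 0.5])
        res = LogGPModel(y, locs, np.zeros(4), field_hp).fit()
        plan = PlannerConfig(n_theta=8, k_mu=1.0, k_sigma=0.0, k_l=0.0)
        fleet = FleetState(own_id=0)
        pos = LocalPosition(300.0, 300.0, 25.0)
        dists = [np.linalg.norm(pos.as_array() - hot)]
        for _ in range(12):
            pos, _ = choose_waypoint(pos, res, 0.0, fleet, plan, field_volume)
            dists.append(np.linalg.norm(pos.as_array() - hot))
        assert np.all(np.diff(dists) < 0)
        assert dists[-1] < 200.0

    def test_separation_pressure_with_large_kl(self, field_volume, field_hp, rng):
        # k_l -> large: the chosen waypoint never reduces the horizontal
        # distance to the other vehicle when an alternative exists
        res = _fitted_model(field_hp, rng)
        plan = PlannerConfig(n_theta=8, k_mu=1.0, k_sigma=1.0, k_l=1e6)
        fleet = FleetState(own_id=0)
        other = LocalPosition(800, 800, 0)
        fleet.update(1, other, 0.0)
        for _ in range(10):
            x_v = LocalPosition(*rng.uniform((100, 100, 5), (1400, 1400, 45)))
            wp, _ = choose_waypoint(x_v, res, 0.0, fleet, plan, field_volume)
            cands = candidate_waypoints(x_v, plan, field_volume)
            d_max = max(c.horizontal_distance(other) for c in cands)
            assert wp.horizontal_distance(other) == pytest.approx(d_max)
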