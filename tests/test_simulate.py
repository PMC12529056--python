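"""Forward simulation: depletion cap, stepping, spread metric, scenarios."""

import numpy as np
import pytest
from shapely.geometry import LineString, box

import mpbspread as mp
from mpbspread.simulate import (
    Scenario,
    SimulationState,
    compute_depletion_cap,
    measure_spread,
    run_ensemble,
    step_simulation,
)


class TestDepletionCap:
    def test_nearest_rank_on_1_to_100(self):
        cum = np.arange(1, 101).reshape(10, 10)
        Q = np.ones((10, 10))
        assert compute_depletion_cap(cum, Q) == 100.0

    def test_all_equal(self):
        cum = np.full((5, 5), 7)
        assert compute_depletion_cap(cum, np.ones((5, 5))) == 7.0

    def test_median_rank(self):
        cum = np.arange(1, 101).reshape(10, 10)
        # position (n-1)*q+1 = 50.5, resolved upward
        assert compute_depletion_cap(cum, np.ones((10, 10)), percentile=50) == 51.0

    def test_jack_only_landscape_raises(self):
        with pytest.raises(ValueError):
            compute_depletion_cap(np.ones((4, 4)), np.zeros((4, 4)))

    def test_only_infested_lodgepole_pixels_qualify(self):
        cum = np.array([[0, 5], [100, 3]])
        Q = np.array([[1.0, 1.0], [0.5, 1.0]])  # 100 is in a hybrid pixel
        assert compute_depletion_cap(cum, Q) == 5.0


def _uniform_landscape(n=21, q=1.0):
    volume = np.full((n, n), 1500.0)
    land = mp.LandscapeGrid(
        volume=volume, Q=np.full((n, n), q), theta=np.full((n, n), 0.6),
        spread_polygon=box(0, 0, n, n).buffer(-0.01),
        projection_line=LineString([(0.5, n / 2), (n - 0.5, n / 2)]),
    )
    return land


class TestMeasureSpread:
    def test_weighted_nearest_rank_oracle(self):
        land = _uniform_landscape(25)
        raster = np.zeros((25, 25), dtype=int)
        # projected distances are x - 0.5 at pixel centers
        raster[12, 0] = 1   # 0 km
        raster[12, 10] = 1  # 10 km
        raster[12, 20] = 98  # 20 km
        assert measure_spread(raster, land, percentile=99.0) == pytest.approx(20.0)
        # brute force on the expanded distribution
        expanded = np.repeat([0.0, 10.0, 20.0], [1, 1, 98])
        rank = int(np.ceil(0.5 * len(expanded)))
        assert measure_spread(raster, land, percentile=50.0) == pytest.approx(
            sorted(expanded)[rank - 1]
        )

    def test_single_pixel_any_percentile(self):
        land = _uniform_landscape(15)
        raster = np.zeros((15, 15), dtype=int)
        raster[7, 9] = 5
        for p in (1, 50, 99, 100):
            assert measure_spread(raster, land, percentile=p) == pytest.approx(9.0)

    def test_rotation_equivariance(self):
        """Rotating raster and geometry together by 90 deg leaves distances."""
        n = 15
        land = _uniform_landscape(n)
        raster = np.zeros((n, n), dtype=int)
        raster[3, 11] = 2
        raster[8, 5] = 1
        d = measure_spread(raster, land)
        rot = np.rot90(raster, -1)  # plane rotation by +90 deg: east -> north
        land_rot = mp.LandscapeGrid(
            volume=land.volume, Q=land.Q, theta=land.theta,
            spread_polygon=land.spread_polygon,
            projection_line=LineString([(n / 2, 0.5), (n / 2, n - 0.5)]),
        )
        assert measure_spread(rot, land_rot) == pytest.approx(d)

    def test_monotone_in_percentile(self, rng):
        land = _uniform_landscape(19)
        raster = rng.poisson(0.4, (19, 19))
        ps = [5, 25, 50, 75, 95, 99]
        vals = [measure_spread(raster, land, percentile=p) for p in ps]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_unweighted_variant(self):
        land = _uniform_landscape(25)
        raster = np.zeros((25, 25), dtype=int)
        raster[12, 0] = 1
        raster[12, 20] = 98
        # unweighted: two locations, median is the lower one
        assert measure_spread(raster, land, percentile=50, weighted=False) == \
            pytest.approx(0.0)

    def test_empty_polygon_flagged_nan(self):
        land = _uniform_landscape(15)
        assert np.isnan(measure_spread(np.zeros((15, 15)), land))

    def test_invalid_percentile(self):
        land = _uniform_landscape(15)
        with pytest.raises(ValueError):
            measure_spread(np.ones((15, 15)), land, percentile=0.0)


@pytest.fixture(scope="module")
def sim_kernel():
    return mp.discretize_kernel(subpixel_n=5, support_radius=21)


@pytest.fixture
def sim_state(rng):
    I0 = np.zeros((21, 21), dtype=np.int64)
    I0[10, 3] = 20
    return SimulationState(year_index=0, I=I0, cumulative=I0.astype(float),
                           depletion_cap=200.0, rng=rng)


class TestStepSimulation:
    def test_zero_survival_annihilates(self, sim_state, true_params_species, sim_kernel):
        land = _uniform_landscape()
        scen = Scenario(name="full_control", survival_series=(0.0,))
        nxt = step_simulation(sim_state, land, true_params_species.params, scen,
                              sim_kernel)
        assert nxt.I.sum() == 0

    def test_capped_pixel_gets_no_new_infestations(self, rng, true_params_species,
                                                   sim_kernel):
        land = _uniform_landscape()
        I0 = np.zeros((21, 21), dtype=np.int64)
        I0[10, 10] = 50
        cum = np.zeros((21, 21))
        cum[10, 10] = 30.0  # already at the cap
        state = SimulationState(year_index=0, I=I0, cumulative=cum,
                                depletion_cap=30.0, rng=rng)
        scen = Scenario(survival_series=(1.0,))
        nxt = step_simulation(state, land, true_params_species.params, scen, sim_kernel)
        assert nxt.I[10, 10] == 0
        assert np.all(nxt.cumulative <= 30.0)

    def test_masked_pixels_stay_zero(self, rng, true_params_species, sim_kernel):
        land = _uniform_landscape()
        land.volume[:, 15:] = 0.2  # east of the line: non-habitat
        I0 = np.zeros((21, 21), dtype=np.int64)
        I0[10, 10] = 40
        state = SimulationState(year_index=0, I=I0, cumulative=I0.astype(float),
                                depletion_cap=500.0, rng=rng)
        nxt = step_simulation(state, land, true_params_species.params,
                              Scenario(survival_series=(1.0,)), sim_kernel)
        assert np.all(nxt.I[:, 15:] == 0)

    def test_mirrored_landscape_gives_mirrored_law(self, rng, true_params_species,
                                                   sim_kernel):
        """Mirroring the source field mirrors beetle pressure and the ZINB
        parameter fields exactly (the spread law is direction-symmetric)."""
        from mpbspread.dispersal import compute_beetle_pressure
        from mpbspread.likelihoods import model1_linear_predictors

        land = _uniform_landscape()
        src = rng.poisson(1.0, (21, 21)).astype(float)
        ones = np.ones((21, 21))
        B = compute_beetle_pressure(src, ones, land.theta, sim_kernel).B
        B_m = compute_beetle_pressure(src[:, ::-1], ones, land.theta, sim_kernel).B
        np.testing.assert_allclose(B_m, B[:, ::-1], rtol=1e-9, atol=1e-12)
        act = B > 0
        pi, mu, _ = model1_linear_predictors(B[act], np.ones(act.sum(), bool),
                                             true_params_species.params)
        pi_m, mu_m, _ = model1_linear_predictors(
            B_m[:, ::-1][act], np.ones(act.sum(), bool), true_params_species.params)
        np.testing.assert_allclose(pi, pi_m, rtol=1e-9)
        np.testing.assert_allclose(mu, mu_m, rtol=1e-9)


class TestScenario:
    def test_attack_equal_override(self, true_params_species):
        scen = Scenario(attack_param_override="jack_equals_lodgepole")
        p = scen.transform_params(true_params_species.params)
        assert p.gamma0_J == p.gamma0_L and p.beta1_J == p.beta1_L

    def test_brood_scale(self, true_params_species):
        p = Scenario(brood_scale=2.0).transform_params(true_params_species.params)
        assert p.c_J == pytest.approx(2.0 * true_params_species.params.c_J)

    def test_q_override_rasters(self):
        land = _uniform_landscape(q=0.3)
        Q, V = Scenario(q_override=1.0).effective_rasters(land)
        assert np.all(Q == 1.0)
        np.testing.assert_array_equal(V, land.volume)

    def test_volume_override_lodgepole_mean(self):
        land = _uniform_landscape(q=1.0)
        land.volume[3, 3] = 0.5  # below threshold: untouched
        Q, V = Scenario(volume_override="lodgepole_mean").effective_rasters(land)
        habitat = land.volume >= 1.0
        assert np.allclose(V[habitat], land.volume[habitat].mean())
        assert V[3, 3] == 0.5

    def test_control_key_disambiguation(self):
        assert Scenario(controlled_series=(0.3,)).survival_for(0) == pytest.approx(0.7)
        assert Scenario(survival_series=(0.3,)).survival_for(5) == pytest.approx(0.3)
        with pytest.raises(ValueError):
            Scenario(survival_series=(0.5,), controlled_series=(0.5,))

    def test_overrides_invalid_for_covariate_model(self):
        p = mp.default_true_params("covariate").params
        with pytest.raises(ValueError):
            Scenario(brood_scale=2.0).transform_params(p)


class TestEnsemble:
    def test_point_mass_deterministic(self, true_params_species, sim_kernel):
        land = _uniform_landscape()
        I0 = np.zeros((21, 21), dtype=np.int64)
        I0[10, 3] = 20
        kwargs = dict(
            initial_I=I0, landscape=land, draws=true_params_species.params,
            scenario=Scenario(survival_series=(0.7,)), n_years=3, n_sims=1,
            seed=13, kernel=sim_kernel, depletion_cap=300.0,
        )
        s1, t1 = run_ensemble(**kwargs)
        s2, t2 = run_ensemble(**kwargs)
        assert t1.equals(t2)
        np.testing.assert_array_equal(s1[0].distance_km, s2[0].distance_km)

    def test_output_table_shape(self, true_params_species, sim_kernel):
        land = _uniform_landscape()
        I0 = np.zeros((21, 21), dtype=np.int64)
        I0[10, 3] = 20
        series, table = run_ensemble(
            I0, land, true_params_species.params, Scenario(survival_series=(0.7,)),
            n_years=4, n_sims=3, seed=2, kernel=sim_kernel, depletion_cap=300.0,
        )
        assert len(series) == 3
        assert set(table.columns) == {"replicate", "year", "distance_km",
                                      "n_infested", "scenario"}
        assert len(table) == 12

    def test_invalid_arguments(self, true_params_species, sim_kernel):
        land = _uniform_landscape()
        I0 = np.zeros((21, 21), dtype=np.int64)
        with pytest.raises(ValueError):
            run_ensemble(I0, land, true_params_species.params, Scenario(),
                         n_years=0, n_sims=1, seed=0, kernel=sim_kernel,
                         depletion_cap=10.0)
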