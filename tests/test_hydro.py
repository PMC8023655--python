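"""Soil water flow: hydraulic functions, root stress, and the Richards
solver's conservation and convergence properties."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import soilplant as sp
from soilplant.hydro import TimeStepControl
from soilplant.params import FeddesParams, RootDistribution, SoilHorizon


class TestRetention:
    def test_saturation_and_dry_limits(self, horizon1):
        assert sp.vgm_retention(0.0, horizon1) == pytest.approx(0.51)
        assert sp.vgm_retention(5.0, horizon1) == pytest.approx(0.51)
        assert sp.vgm_retention(-1e9, horizon1) == pytest.approx(0.18,
                                                                 abs=1e-3)

    def test_closed_form_value(self, horizon1):
        # independent evaluation of the retention formula at h = -100 cm
        assert sp.vgm_retention(-100.0, horizon1) == pytest.approx(
            0.37668553407038985, rel=1e-12)

    def test_inverse_round_trip(self, horizon1):
        for h in (-5.0, -100.0, -3000.0):
            theta = sp.vgm_retention(h, horizon1)
            assert sp.vgm_pressure_head(theta, horizon1) == pytest.approx(
                h, rel=1e-9)

    @given(h=st.floats(-1e6, -1e-3))
    def test_monotone_and_bounded(self, h):
        hor = SoilHorizon(0.18, 0.51, 0.013, 2.07, 70.0, 0.0, -10.0)
        th = sp.vgm_retention(h, hor)
        assert 0.18 <= th <= 0.51
        assert sp.vgm_retention(h * 0.5, hor) >= th

    def test_nonfinite_rejected(self, horizon1):
        with pytest.raises(ValueError):
            sp.vgm_retention(np.nan, horizon1)


class TestConductivity:
    def test_saturated_equals_ks(self, horizon1):
        assert sp.vgm_conductivity(0.0, horizon1) == pytest.approx(70.0)

    def test_dry_limit_zero(self, horizon1):
        assert sp.vgm_conductivity(-1e9, horizon1) == pytest.approx(
            0.0, abs=1e-12)

    def test_closed_form_value(self, horizon1):
        assert sp.vgm_conductivity(-50.0, horizon1) == pytest.approx(
            14.26553992164242, rel=1e-12)


class TestFeddes:
    def test_plateau_wilting_and_ramp(self):
        p = FeddesParams()
        assert sp.feddes_stress(-30.0, 1.0, p) == pytest.approx(1.0)
        assert sp.feddes_stress(-8000.0, 1.0, p) == pytest.approx(0.0)
        # midpoint of the (P0, POpt) anoxia ramp
        assert sp.feddes_stress(-22.5, 1.0, p) == pytest.approx(0.5)

    def test_p2_interpolates_with_transpiration_demand(self):
        p = FeddesParams()
        h = -450.0  # between P2H and the interpolated P2 at mid demand
        hi = sp.feddes_stress(h, p.r2H, p)
        lo = sp.feddes_stress(h, p.r2L, p)
        mid = sp.feddes_stress(h, 0.5 * (p.r2H + p.r2L), p)
        assert hi < mid < lo == 1.0

    @given(h=st.floats(-1e5, 10.0), tp=st.floats(0.0, 3.0))
    def test_bounded(self, h, tp):
        a = sp.feddes_stress(h, tp, FeddesParams())
        assert 0.0 <= a <= 1.0

    def test_piecewise_linear_continuity(self):
        p = FeddesParams()
        h = np.linspace(-9000.0, 5.0, 20001)
        dx = h[1] - h[0]
        a = sp.feddes_stress(h, 1.0, p)
        # steps never exceed the steepest ramp slope (the anoxia ramp,
        # 1/(P0 - POpt) per cm) -> the function has no jumps
        assert np.max(np.abs(np.diff(a))) <= dx / (p.P0 - p.POpt) * 1.05


class TestRootDensity:
    def test_normalization_all_times(self, grid):
        roots = RootDistribution(growth_rate=0.2)
        for t in (0.0, 5.0, 20.0, 48.0):
            b = sp.root_density_profile(t, roots, grid)
            assert b @ grid.w_cv == pytest.approx(1.0, rel=1e-12)
            assert np.all(b >= 0.0)

    def test_seed_stage_concentrated_at_surface(self, grid):
        roots = RootDistribution(growth_rate=0.2, depth0=2.0)
        b = sp.root_density_profile(0.0, roots, grid)
        assert np.all(b[grid.z < -2.0] == 0.0)
        assert b[-1] > 0.0

    def test_profile_matches_closed_form(self, grid):
        # triangular density to a logistically growing front, normalized
        roots = RootDistribution(growth_rate=0.2)
        t = 48.0
        L = roots.rooted_depth(t)
        w = np.maximum(1.0 - (-grid.z) / L, 0.0)
        expected = w / (w @ grid.w_cv)
        np.testing.assert_allclose(
            sp.root_density_profile(t, roots, grid), expected, rtol=1e-12)

    def test_front_grows_logistically(self):
        roots = RootDistribution(growth_rate=0.2, depth0=2.0, depth_max=20.0)
        assert roots.rooted_depth(0.0) == pytest.approx(2.0)
        assert roots.rooted_depth(200.0) == pytest.approx(20.0, rel=1e-6)


class TestPartitionEt:
    def test_limits_and_value(self):
        ep, tp = sp.partition_et(0.7, 0.0)
        assert (ep, tp) == (0.7, 0.0)
        ep, tp = sp.partition_et(0.7, 1e6)
        assert ep == pytest.approx(0.0, abs=1e-12)
        ep, tp = sp.partition_et(0.5, 2.0)
        assert tp == pytest.approx(0.3019324570722223, rel=1e-12)
        assert ep + tp == pytest.approx(0.5)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sp.partition_et(-0.1, 1.0)


class TestRichardsSolver:
    def test_mass_balance_and_theta_bounds(self, median_forward):
        flow = median_forward.flow
        assert flow.ledger["mass_balance_error_rel"] < 0.005
        assert np.all(flow.theta >= 0.18 - 1e-9)
        assert np.all(flow.theta <= 0.51 + 1e-9)

    def test_no_bottom_outflow_in_reference_scenario(self, median_forward):
        assert median_forward.flow.ledger["bottom_outflow"] == 0.0

    def test_zero_forcing_reaches_hydrostatic_rest(self, scenario, grid):
        n = 48
        forcing = sp.Forcing(t=np.arange(n, dtype=float),
                             irrigation=np.zeros(n), et=np.zeros(n),
                             lai=np.zeros(n))
        flow = sp.solve_richards(grid, scenario.horizons, forcing,
                                 scenario.feddes, scenario.roots, 0.24)
        # storage conserved (nothing enters or leaves) ...
        w = grid.w_cv
        assert flow.theta[-1] @ w == pytest.approx(flow.theta[0] @ w,
                                                   rel=1e-6)
        # ... and internal fluxes decay toward equilibrium
        assert np.max(np.abs(flow.q_face[-1])) < 1e-3

    def test_zero_transpiration_means_zero_uptake(self, scenario, grid):
        n = 20
        forcing = sp.Forcing(t=np.arange(n, dtype=float),
                             irrigation=np.full(n, 0.3),
                             et=np.full(n, 0.4),
                             lai=np.zeros(n))  # LAI = 0 -> Tp = 0
        flow = sp.solve_richards(grid, scenario.horizons, forcing,
                                 scenario.feddes, scenario.roots, 0.24)
        assert np.all(flow.Ta == 0.0)
        assert np.all(flow.sink == 0.0)

    def test_head_continuous_across_horizon_interface(self, median_forward):
        # the uniform-theta initial condition is discontinuous in h by
        # construction, and during deep dry-down K -> 0 decouples the
        # nodes; whenever the interface region is moist enough to be
        # hydraulically coupled, the head must be continuous
        flow = median_forward.flow
        z = flow.grid.z
        near = np.sort(np.argsort(np.abs(z + 10.0))[:2])
        later = flow.t >= 1.0
        h_pair = flow.h[later][:, near]
        moist = np.all(np.abs(h_pair) < 500.0, axis=1)
        assert moist.sum() > 10
        gap = np.abs(h_pair[moist, 0] - h_pair[moist, 1])
        scale = np.abs(h_pair[moist, 0]) + 1.0
        assert np.all(gap / scale < 0.5)

    def test_refinement_convergence_of_reference_scenario(
            self, scenario, forcing):
        coarse = sp.make_grid(scenario.horizons, n_elements=50)
        fine = sp.make_grid(scenario.horizons, n_elements=100)
        ctl_c = TimeStepControl(dt_max=0.2)
        ctl_f = TimeStepControl(dt_max=0.1)
        fc = sp.solve_richards(coarse, scenario.horizons, forcing,
                               scenario.feddes, scenario.roots, 0.24,
                               dt_control=ctl_c)
        ff = sp.solve_richards(fine, scenario.horizons, forcing,
                               scenario.feddes, scenario.roots, 0.24,
                               dt_control=ctl_f)
        avg_c = fc.column_average_theta()[-1]
        avg_f = ff.column_average_theta()[-1]
        assert abs(avg_c - avg_f) / avg_f < 0.002

    def test_infiltration_matches_refined_reference(self, scenario):
        # wetting front into a moderately dry column vs an 8x refined
        # solution of the same problem
        n = 10
        forcing = sp.Forcing(t=np.arange(n, dtype=float),
                             irrigation=np.full(n, 1.0),
                             et=np.zeros(n), lai=np.zeros(n))
        coarse = sp.make_grid(scenario.horizons, n_elements=25)
        fine = sp.make_grid(scenario.horizons, n_elements=200)
        fc = sp.solve_richards(coarse, scenario.horizons, forcing,
                               scenario.feddes, scenario.roots, 0.24,
                               dt_control=TimeStepControl(dt_max=0.2))
        ff = sp.solve_richards(fine, scenario.horizons, forcing,
                               scenario.feddes, scenario.roots, 0.24,
                               dt_control=TimeStepControl(dt_max=0.05))
        th_c = np.interp(fine.z, coarse.z, fc.theta[-1])
        th_f = ff.theta[-1]
        l2 = np.linalg.norm(th_c - th_f) / np.linalg.norm(th_f)
        assert l2 < 0.01

    def test_unphysical_initial_state_rejected(self, scenario, grid):
        n = 5
        forcing = sp.Forcing(t=np.arange(n, dtype=float),
                             irrigation=np.zeros(n), et=np.zeros(n),
                             lai=np.zeros(n))
        with pytest.raises(ValueError):
            sp.solve_richards(grid, scenario.horizons, forcing,
                              scenario.feddes, scenario.roots, 0.9)


class TestGridAndTypes:
    def test_grid_is_top_refined_and_spans_column(self, scenario):
        g = sp.make_grid(scenario.horizons, n_elements=100)
        assert g.n_elements == 100
        assert g.z[0] == pytest.approx(-20.0)
        assert g.z[-1] == 0.0
        assert np.all(np.diff(g.z) > 0)
        assert g.dz_face[-1] <= 0.05 + 1e-12  # surface element
        assert g.w_cv.sum() == pytest.approx(20.0)

    def test_horizon_validation(self):
        with pytest.raises(ValueError, match="n must exceed 1"):
            SoilHorizon(0.18, 0.51, 0.013, 0.9, 70.0, 0.0, -10.0)
        with pytest.raises(ValueError):
            SoilHorizon(0.6, 0.51, 0.013, 2.0, 70.0, 0.0, -10.0)

    def test_feddes_ordering_validated(self):
        with pytest.raises(ValueError):
            FeddesParams(P0=-40.0, POpt=-30.0)

    def test_forcing_partition_consistency(self):
        n = 3
        with pytest.raises(ValueError):
            sp.Forcing(t=np.arange(n, dtype=float),
                       irrigation=np.zeros(n), et=np.ones(n),
                       lai=np.zeros(n), ep=np.zeros(n),
                       tp=np.full(n, 0.5))
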