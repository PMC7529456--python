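import numpy as np
import pytest

from cordclose.constitutive import MMHG_TO_KPA
from cordclose.equilibrium import radius_map

from _oracles import energy_minimum_radius


class TestRadiusMap:
    def test_identity_at_reference(self, params):
        r = radius_map(params.geometry.A, params.geometry, v=1.0, lambda_z=1.0)
        R = np.linspace(params.geometry.A, params.geometry.C, 7)
        assert np.allclose(r(R), R, rtol=1e-12)

    def test_outer_radius_closed_form(self, params):
        g = params.geometry
        a = g.A
        r = radius_map(a, g, v=1.0, lambda_z=1.28)
        expected = np.sqrt(a**2 + (g.C**2 - g.A**2) / 1.28)
        assert r(g.C) == pytest.approx(expected, rel=1e-12)

    def test_swelling_scales_inner_annulus_volume(self, params):
        g = params.geometry
        a = 150.0
        r1 = radius_map(a, g, v=1.0, lambda_z=1.28)
        r05 = radius_map(a, g, v=0.5, lambda_z=1.28)
        vol1 = r1(g.B) ** 2 - a**2
        vol05 = r05(g.B) ** 2 - a**2
        assert vol05 == pytest.approx(0.5 * vol1, rel=1e-12)

    def test_negative_inner_radius_rejected(self, params):
        from cordclose.equilibrium import InfeasibleGeometryError
        with pytest.raises(InfeasibleGeometryError):
            radius_map(-1.0, params.geometry)


class TestLuminalPressure:
    def test_reference_state_is_unpressurized(self, params):
        from dataclasses import replace
        from cordclose import BilayerVesselModel, VesselParameters
        g = replace(params.geometry, lambda_z=1.0)
        m = BilayerVesselModel(VesselParameters(geometry=g, inner=params.inner,
                                                outer=params.outer, tone=params.tone))
        assert m.luminal_pressure(g.A) == pytest.approx(0.0, abs=1e-12)

    def test_pressure_consistent_with_solved_radius(self, model):
        st = model.solve(25.0)
        P = model.luminal_pressure(st.a)
        assert P == pytest.approx(25.0 * MMHG_TO_KPA, abs=1e-6)

    def test_active_stress_raises_pressure_at_fixed_radius(self, model):
        a = 250.0
        P = [model.luminal_pressure(a, T_act=T) for T in (0.0, 20.0, 40.0)]
        assert P[0] < P[1] < P[2]


class TestSolve:
    def test_unloaded_configuration_recovers_reference(self, params):
        from dataclasses import replace
        from cordclose import BilayerVesselModel, VesselParameters
        g = replace(params.geometry, lambda_z=1.0)
        m = BilayerVesselModel(VesselParameters(geometry=g, inner=params.inner,
                                                outer=params.outer, tone=params.tone))
        st = m.solve(0.0)
        assert st.a == pytest.approx(params.geometry.A, abs=1e-5)

    def test_boundary_conditions_on_radial_stress(self, model):
        st = model.solve(25.0, T_act=40.0, v=0.5)
        assert st.sigma_rr[0] == pytest.approx(-st.pressure_kpa, rel=1e-9)
        assert abs(st.sigma_rr[-1]) < 1e-4 * st.pressure_kpa
        # continuity at the interface (profile duplicates the interface node)
        inner_end = st.sigma_rr[st.layer == 0][-1]
        outer_start = st.sigma_rr[st.layer == 1][0]
        assert inner_end == pytest.approx(outer_start, abs=1e-9)

    @pytest.mark.parametrize("v", [0.5, 1.0, 2.0])
    def test_per_layer_volume_constraints(self, model, v):
        """Deformed/reference volume ratio = v (inner) and 1 (outer)."""
        st = model.solve(25.0, T_act=30.0, v=v)
        lz = st.lambda_z
        for layer, target in ((0, v), (1, 1.0)):
            sel = st.layer == layer
            r, R = st.r[sel], st.R[sel]
            vol_def = lz * np.trapezoid(r, r)      # per unit reference length
            vol_ref = np.trapezoid(R, R)
            assert vol_def / vol_ref == pytest.approx(target, rel=1e-6)

    def test_agrees_with_energy_minimization_oracle(self, model, rng):
        """Equilibrium radius matches direct total-potential minimization."""
        for _ in range(10):
            P = rng.uniform(2.0, 30.0)
            T = rng.uniform(0.0, 80.0)
            v = rng.uniform(0.5, 2.0)
            st = model.solve(P, T_act=T, v=v)
            if st.occluded:
                continue
            a_oracle = energy_minimum_radius(model, P, T_act=T, v=v)
            assert st.a == pytest.approx(a_oracle, rel=1e-3)

    def test_swelling_narrows_passive_lumen(self, model):
        a1 = model.solve(25.0, v=1.0).a
        a2 = model.solve(25.0, v=2.0).a
        assert a2 < a1

    def test_volume_loss_aids_narrowing_under_strong_tone(self, model):
        a_low = model.solve(25.0, T_act=120.0, v=0.5).a
        a_high = model.solve(25.0, T_act=120.0, v=1.0).a
        assert a_low < a_high

    def test_radius_nonincreasing_in_active_stress(self, model):
        a_vals = [model.solve(25.0, T_act=T, v=1.0).a
                  for T in np.linspace(0.0, 150.0, 16)]
        assert all(a2 <= a1 + 1e-9 for a1, a2 in zip(a_vals, a_vals[1:]))

    def test_negative_pressure_rejected(self, model):
        with pytest.raises(ValueError):
            model.solve(-5.0)


@pytest.fixture(scope="module")
def curves(model):
    grid = np.linspace(0.0, 150.0, 76)
    return model.closure_sweep(25.0, grid, [0.5, 1.0])


class TestClosureCurves:
    def test_normalized_radius_starts_at_one(self, curves):
        for c in curves:
            assert c.a_normalized[0] == pytest.approx(1.0, rel=1e-12)

    def test_monotone_non_increasing(self, curves):
        for c in curves:
            d = np.diff(c.a_normalized)
            assert np.all(d <= 1e-9)

    def test_sharper_transition_at_lower_swelling(self, curves):
        low_v = min(curves, key=lambda c: c.v)
        high_v = max(curves, key=lambda c: c.v)
        assert low_v.max_slope > high_v.max_slope

    def test_plateau_at_large_active_stress(self, curves):
        for c in curves:
            assert c.plateau_reached(tol_per_kpa=0.5)

    def test_tidy_frame_columns(self, curves):
        df = curves[0].to_frame()
        for col in ("v", "P_mmHg", "T_act_kPa", "a_um", "a_normalized",
                    "f_axial_mN"):
            assert col in df.columns


class TestSwellingCrossover:
    def test_identical_volumes_rejected(self, model):
        with pytest.raises(ValueError):
            model.swelling_crossover(25.0, 1.0, 1.0)

    def test_crossover_near_fifty_kpa(self, model):
        x = model.swelling_crossover(25.0, 0.5, 1.0)
        assert x is not None
        assert 35.0 <= x <= 65.0

    def test_crossover_invariant_to_grid_refinement(self, model):
        coarse = model.swelling_crossover(25.0, 0.5, 1.0,
                                          T_act_grid=np.linspace(0, 150, 31))
        fine = model.swelling_crossover(25.0, 0.5, 1.0,
                                        T_act_grid=np.linspace(0, 150, 151))
        assert abs(coarse - fine) < 1.0


class TestUniformWall:
    def test_positive_inner_stress_at_matched_narrowing(self, model, uniform_model):
        """At comparable luminal narrowing the single-material wall keeps a
        non-compressive inner half while the bilayer is strongly compressed."""
        a0_uni = uniform_model.solve(25.0, T_act=0.0, v=1.0).a
        a0_bi = model.solve(25.0, T_act=0.0, v=0.5).a
        st_uni = uniform_model.solve(25.0, T_act=25.0, v=1.0)
        st_bi = model.solve(25.0, T_act=100.0, v=0.5)
        # both walls narrowed to a similar fraction of their passive radius
        assert st_uni.a / a0_uni == pytest.approx(st_bi.a / a0_bi, abs=0.1)
        assert st_uni.mean_sigma_tt_inner > 0.0
        assert st_bi.mean_sigma_tt_inner < -2.0

    def test_axial_force_is_reported(self, model):
        st = model.solve(25.0)
        assert np.isfinite(st.f_axial)
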