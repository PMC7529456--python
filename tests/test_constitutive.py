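import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from cordclose.constitutive import (
    ActiveTone,
    FiberFamily,
    LayerMaterial,
    VesselGeometry,
    active_pseudo_energy,
    active_stress,
    active_stress_derivative,
    fiber_stretch,
    passive_extra_stress,
    strain_energy,
    wall_derivatives,
)

# physiological range: beyond ~1.6 the exponential fiber energy reaches
# ~1e15 kPa and floating-point differencing of W is meaningless
stretches = st.floats(0.6, 1.6)


class TestTypes:
    def test_geometry_ordering_enforced(self):
        with pytest.raises(ValueError):
            VesselGeometry(A=200.0, B=150.0, C=250.0)

    def test_tone_window_enforced(self):
        with pytest.raises(ValueError):
            ActiveTone(T_act=10.0, lambda_m=0.1, lambda_0=0.2)

    def test_fiber_angle_range(self):
        with pytest.raises(ValueError):
            FiberFamily(c1=1.0, c2=1.0, eta=120.0)


class TestFiberStretch:
    @pytest.mark.parametrize(
        "lt, lz, eta, expected",
        [
            (1.7, 1.28, 0.0, 1.28),     # axial family sees only lambda_z
            (1.7, 1.28, 90.0, 1.7),     # circumferential family sees only lambda_theta
            (1.7, 1.28, 41.92,
             np.sqrt(1.28**2 * np.cos(np.deg2rad(41.92))**2
                     + 1.7**2 * np.sin(np.deg2rad(41.92))**2)),
        ],
    )
    def test_examples(self, lt, lz, eta, expected):
        assert fiber_stretch(lt, lz, eta) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_stretch(self):
        with pytest.raises(ValueError):
            fiber_stretch(-1.0, 1.0, 45.0)


class TestPassiveStress:
    def test_reference_state_is_isotropic(self, outer_material):
        srr, stt, szz = passive_extra_stress(1.0, 1.0, 1.0, outer_material)
        mu = outer_material.mu
        assert srr == pytest.approx(mu)
        assert stt == pytest.approx(mu)
        assert szz == pytest.approx(mu)

    def test_neo_hookean_closed_form(self, inner_material):
        lr, lt, lz = 0.7, 1.4, 1.28
        srr, stt, szz = passive_extra_stress(lr, lt, lz, inner_material)
        mu = inner_material.mu
        assert srr == pytest.approx(mu * lr**2)
        assert stt == pytest.approx(mu * lt**2)
        assert szz == pytest.approx(mu * lz**2)

    def test_stretched_outer_layer_is_anisotropic(self, outer_material):
        srr, stt, szz = passive_extra_stress(0.6, 1.6, 1.28, outer_material)
        assert np.isfinite(stt) and stt > srr > 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(lr=stretches, lt=stretches, lz=stretches)
    def test_stress_is_stretch_times_energy_gradient(self, lr, lt, lz, outer_material):
        """sigma_i = l_i dW/dl_i, checked by central differences of W.

        The tension-only fiber clamp makes W only C1 exactly at unit fiber
        stretch, so configurations within the difference stencil of that
        kink are excluded.
        """
        from cordclose.constitutive import fiber_stretch
        for fam in outer_material.fibers:
            assume(abs(float(fiber_stretch(lt, lz, fam.eta)) - 1.0) > 1e-3)
        srr, stt, szz = passive_extra_stress(lr, lt, lz, outer_material)
        # W is exactly quadratic in lambda_r, so a wide radial stencil is
        # exact and immune to roundoff against the large fiber energy
        for val, axis, sig, h in ((lr, 0, srr, 0.1), (lt, 1, stt, 1e-5),
                                  (lz, 2, szz, 1e-5)):
            args = [lr, lt, lz]

            def W_of(x):
                a = list(args)
                a[axis] = x
                return strain_energy(*a, outer_material)

            dW = (W_of(val + h) - W_of(val - h)) / (2 * h)
            assert sig == pytest.approx(val * dW, rel=1e-6, abs=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(lk=st.floats(1.0, 1.8), scale=st.floats(0.1, 10.0))
    def test_fiber_tension_only_monotone_and_homogeneous(self, lk, scale):
        fam = FiberFamily(c1=2.0, c2=1.5, eta=90.0)
        mat = LayerMaterial(mu=1e-9, fibers=(fam,))
        mat_scaled = LayerMaterial(mu=1e-9, fibers=(
            FiberFamily(c1=scale * fam.c1, c2=fam.c2, eta=fam.eta),))
        _, s1, _ = passive_extra_stress(1.0, lk, 1.0, mat)
        _, s2, _ = passive_extra_stress(1.0, lk + 1e-3, 1.0, mat)
        _, s_scaled, _ = passive_extra_stress(1.0, lk, 1.0, mat_scaled)
        assert s1 >= 0.0
        assert s2 >= s1  # increasing in fiber stretch
        assert s_scaled - 1e-9 * lk**2 == pytest.approx(
            scale * (s1 - 1e-9 * lk**2), rel=1e-9, abs=1e-12)

    def test_compressed_fibers_carry_no_load(self):
        mat = LayerMaterial(mu=1.0, fibers=(FiberFamily(c1=5.0, c2=2.0, eta=90.0),))
        _, stt, _ = passive_extra_stress(1.2, 0.8, 1.0, mat)
        assert stt == pytest.approx(1.0 * 0.8**2)  # matrix only

    def test_stress_linear_in_mu(self):
        m1 = LayerMaterial(mu=1.0)
        m3 = LayerMaterial(mu=3.0)
        s1 = passive_extra_stress(0.8, 1.3, 1.1, m1)
        s3 = passive_extra_stress(0.8, 1.3, 1.1, m3)
        assert np.allclose(np.asarray(s3), 3.0 * np.asarray(s1))


class TestActiveStress:
    tone = ActiveTone(T_act=50.0, lambda_m=2.5, lambda_0=0.2)

    def test_zero_at_lower_contractile_limit(self):
        assert active_stress(0.2, self.tone) == pytest.approx(0.0)

    def test_peak_value_at_lambda_m(self):
        assert active_stress(2.5, self.tone) == pytest.approx(125.0)

    def test_midpoint_value(self):
        expected = 50.0 * 1.35 * (1.0 - (1.15 / 2.3) ** 2)
        assert active_stress(1.35, self.tone) == pytest.approx(expected, rel=1e-12)

    def test_continuous_over_positive_stretches(self):
        lt = np.linspace(0.01, 6.0, 20001)
        t = active_stress(lt, self.tone)
        jumps = np.abs(np.diff(t))
        assert jumps.max() < 0.1  # no discontinuity at the clamping edges

    def test_clamped_below_window(self):
        assert active_stress(0.05, self.tone) == 0.0

    def test_linear_in_magnitude(self):
        t1 = active_stress(1.4, self.tone.with_magnitude(10.0))
        t2 = active_stress(1.4, self.tone.with_magnitude(30.0))
        assert t2 == pytest.approx(3.0 * t1)

    def test_derivative_matches_finite_difference(self):
        lt = np.array([0.5, 1.0, 1.5, 2.0])
        h = 1e-7
        fd = (active_stress(lt + h, self.tone) - active_stress(lt - h, self.tone)) / (2 * h)
        assert np.allclose(active_stress_derivative(lt, self.tone), fd, rtol=1e-5)

    def test_pseudo_energy_generates_the_stress(self):
        lt = np.array([0.6, 1.1, 1.9])
        h = 1e-7
        dW = (active_pseudo_energy(lt + h, self.tone)
              - active_pseudo_energy(lt - h, self.tone)) / (2 * h)
        assert np.allclose(lt * dW, active_stress(lt, self.tone), rtol=1e-5)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            ActiveTone(T_act=1.0, lambda_m=0.2, lambda_0=0.2)


class TestWallDerivatives:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(lr=stretches, lt=stretches)
    def test_second_derivatives_match_finite_differences(self, lr, lt, outer_material):
        from cordclose.constitutive import fiber_stretch
        lz = 1.28
        for fam in outer_material.fibers:
            assume(abs(float(fiber_stretch(lt, lz, fam.eta)) - 1.0) > 1e-3)
        d = wall_derivatives(lr, lt, lz, outer_material)
        h = 1e-6

        # energy gradient from the (independently verified) extra stresses:
        # W_i = sigma_i / l_i; differencing it avoids the cancellation of
        # second differences of the large fiber energy itself
        def Wr_of(lr_):
            return passive_extra_stress(lr_, lt, lz, outer_material)[0] / lr_

        def Wt_of(lt_):
            return passive_extra_stress(lr, lt_, lz, outer_material)[1] / lt_

        Wrr = (Wr_of(lr + h) - Wr_of(lr - h)) / (2 * h)
        Wtt = (Wt_of(lt + h) - Wt_of(lt - h)) / (2 * h)
        assert d["Wtt"] == pytest.approx(Wtt, rel=1e-5, abs=1e-8)
        assert d["Wrr"] == pytest.approx(Wrr, rel=1e-5, abs=1e-8)
        assert d["Wrt"] == pytest.approx(0.0, abs=1e-9)

    def test_active_contribution_consistent_with_tone_law(self, outer_material):
        tone = ActiveTone(T_act=40.0)
        lt = 1.3
        passive = wall_derivatives(0.8, lt, 1.28, outer_material)
        total = wall_derivatives(0.8, lt, 1.28, outer_material, tone=tone)
        assert lt * (total["Wt"] - passive["Wt"]) == pytest.approx(
            active_stress(lt, tone), rel=1e-12)
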