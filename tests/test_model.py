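"""Forward two-pool model: lineshapes, pulse power, steady-state signal."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from mpfmap.model import (
    AcquisitionProtocol,
    MTPulse,
    TwoPoolConstraints,
    VoxelTissueParams,
    gaussian_lineshape,
    lorentzian_lineshape,
    pulse_rms_amplitude,
    saturation_rates,
    spoiled_gre_signal,
    steady_state_signal,
    super_lorentzian_lineshape,
    two_pool_signal,
)

from _oracles import numeric_pulse_rms, ode_steady_state_signal


class TestLorentzian:
    def test_on_resonance_closed_form(self):
        assert lorentzian_lineshape(0.05, 0.0) == pytest.approx(0.05 / math.pi)

    def test_decreasing_in_offset_and_vanishing(self):
        offs = np.array([0.0, 10.0, 1e3, 1e5, 1e8])
        g = lorentzian_lineshape(0.0367, offs)
        assert np.all(np.diff(g) < 0)
        assert g[-1] < 1e-12

    def test_value_matches_closed_form_oracle(self):
        # independent high-precision evaluation of (T2/pi)/(1+(2 pi d T2)^2)
        t2, off = 0.0367, 1500.0
        expected = (t2 / math.pi) / (1.0 + (2.0 * math.pi * off * t2) ** 2)
        assert lorentzian_lineshape(t2, off) == pytest.approx(expected, rel=1e-14)

    def test_invalid_t2_raises(self):
        with pytest.raises(ValueError):
            lorentzian_lineshape(0.0, 100.0)


class TestSuperLorentzian:
    def test_matches_quadrature_oracle(self):
        # direct adaptive quadrature of the orientation integral at tight tol
        t2b, off = 10e-6, 1500.0
        c = 2 * math.pi * off * t2b

        def integrand(u):
            d = abs(3 * u * u - 1)
            if d == 0:
                return 0.0
            return math.sqrt(2 / math.pi) / d * math.exp(-2 * (c / d) ** 2)

        ref, _ = quad(integrand, 0, 1, points=[1 / math.sqrt(3)],
                      limit=500, epsabs=0, epsrel=1e-12)
        ref *= t2b
        assert super_lorentzian_lineshape(t2b, off) == pytest.approx(ref, rel=1e-6)

    def test_monotone_decay_in_offset(self):
        offs = np.linspace(1e3, 20e3, 10)
        g = super_lorentzian_lineshape(10e-6, offs)
        assert np.all(np.diff(g) < 0)

    @pytest.mark.parametrize("c", [0.5, 2.0, 5.0])
    def test_scale_invariance(self, c):
        # g(T2, off) = T2 * G(off*T2) implies g(c T2, off/c) = c g(T2, off)
        g1 = super_lorentzian_lineshape(10e-6, 1500.0)
        g2 = super_lorentzian_lineshape(c * 10e-6, 1500.0 / c)
        assert g2 / c == pytest.approx(g1, rel=1e-8)

    def test_on_resonance_is_domain_error(self):
        with pytest.raises(ValueError):
            super_lorentzian_lineshape(10e-6, 0.0)


class TestPulsePower:
    def test_rectangular_closed_form(self):
        pulse = MTPulse(1500.0, 500.0, 7.68e-3, envelope_shape="rectangular")
        assert pulse_rms_amplitude(pulse) == pytest.approx(
            math.radians(500.0) / 7.68e-3, rel=1e-14)

    def test_gaussian_matches_numeric_integration(self):
        pulse = MTPulse(1500.0, 500.0, 7.68e-3, truncation_level=0.01)
        assert pulse_rms_amplitude(pulse) == pytest.approx(
            numeric_pulse_rms(pulse), rel=1e-6)

    def test_gaussian_exceeds_rectangular_at_equal_flip(self):
        gauss = MTPulse(1500.0, 500.0, 7.68e-3)
        rect = MTPulse(1500.0, 500.0, 7.68e-3, envelope_shape="rectangular")
        assert pulse_rms_amplitude(gauss) > pulse_rms_amplitude(rect)

    def test_invalid_pulse_rejected(self):
        with pytest.raises(ValueError):
            MTPulse(1500.0, 500.0, -1.0)
        with pytest.raises(ValueError):
            MTPulse(1500.0, 500.0, 7.68e-3, truncation_level=1.5)


class TestSaturationRates:
    def test_compose_lineshape_oracles(self, constraints):
        pulse = MTPulse(1500.0, 500.0, 7.68e-3)
        r1 = 1.5
        wf, wb = saturation_rates(pulse, constraints, r1)
        w1 = pulse_rms_amplitude(pulse)
        t2f = constraints.r1t2_free / r1
        assert wf == pytest.approx(
            math.pi * w1 ** 2 * lorentzian_lineshape(t2f, 1500.0), rel=1e-12)
        assert wb == pytest.approx(
            math.pi * w1 ** 2 * super_lorentzian_lineshape(10e-6, 1500.0),
            rel=1e-8)

    def test_bound_rate_dominates_at_clinical_offset(self, constraints):
        pulse = MTPulse(1500.0, 500.0, 7.68e-3)
        wf, wb = saturation_rates(pulse, constraints, 1.5)
        assert wb > 10 * wf

    def test_gaussian_bound_lineshape_variant(self):
        c = TwoPoolConstraints(bound_lineshape="gaussian")
        pulse = MTPulse(1500.0, 500.0, 7.68e-3)
        w1 = pulse_rms_amplitude(pulse)
        _, wb = saturation_rates(pulse, c, 1.0)
        assert wb == pytest.approx(
            math.pi * w1 ** 2 * gaussian_lineshape(10e-6, 1500.0), rel=1e-12)


class TestSteadyStateSignal:
    def test_ernst_limit_grid(self):
        # f = 0, no MT pulse: reduces to the closed-form spoiled-GRE signal
        for r1 in (0.3, 0.8, 1.5, 3.0):
            for tr in (0.01, 0.016, 0.02, 0.05):
                for alpha in (3.0, 8.0, 18.0, 45.0):
                    prot = AcquisitionProtocol(tr, alpha)
                    s2p = two_pool_signal(0.0, r1, prot)
                    ernst = spoiled_gre_signal(1.0, r1, tr, alpha)
                    assert abs(s2p - ernst) / ernst < 1e-10

    def test_matches_ode_oracle_random_draws(self, protocols, constraints):
        rng = np.random.default_rng(42)
        for _ in range(6):
            f = rng.uniform(0.005, 0.3)
            r1 = rng.uniform(0.5, 2.5)
            s = two_pool_signal(f, r1, protocols["mtw"], constraints)
            ref = ode_steady_state_signal(f, r1, protocols["mtw"], constraints)
            assert abs(s - ref) / abs(ref) < 1e-6

    def test_monotone_decreasing_in_f(self, protocols, constraints):
        fs = np.linspace(0.0, 0.3, 61)
        sig = two_pool_signal(fs, 1.2, protocols["mtw"], constraints)
        assert np.all(np.diff(sig) < 0)

    def test_more_bound_pool_means_less_signal(self, protocols, constraints):
        s_hi = two_pool_signal(0.13, 1.5, protocols["mtw"], constraints)
        s_lo = two_pool_signal(0.05, 1.5, protocols["mtw"], constraints)
        assert s_hi < s_lo

    def test_offset_sign_symmetry(self, constraints):
        base = dict(effective_flip_angle=500.0, duration=7.68e-3)
        p_pos = AcquisitionProtocol(0.02, 8.0, mt_pulse=MTPulse(1500.0, **base))
        p_neg = AcquisitionProtocol(0.02, 8.0, mt_pulse=MTPulse(-1500.0, **base))
        s_pos = two_pool_signal(0.1, 1.2, p_pos, constraints)
        s_neg = two_pool_signal(0.1, 1.2, p_neg, constraints)
        assert s_pos == pytest.approx(s_neg, rel=1e-14)

    @settings(max_examples=25, deadline=None)
    @given(pd=st.floats(0.1, 10.0), f=st.floats(0.0, 0.3),
           r1=st.floats(0.3, 3.0))
    def test_homogeneous_in_pd(self, protocols, constraints, pd, f, r1):
        s1 = two_pool_signal(f, r1, protocols["mtw"], constraints, pd=1.0)
        spd = two_pool_signal(f, r1, protocols["mtw"], constraints, pd=pd)
        assert spd == pytest.approx(pd * s1, rel=1e-12)

    def test_voxel_wrapper(self, protocols, constraints):
        vox = VoxelTissueParams(mpf=0.1, r1=1.2, pd=2.0)
        s = steady_state_signal(vox, protocols["mtw"], constraints)
        assert s == pytest.approx(
            two_pool_signal(0.1, 1.2, protocols["mtw"], constraints, pd=2.0))


class TestSpoiledGre:
    def test_small_flip_limit(self):
        assert spoiled_gre_signal(1.0, 1.0, 0.016, 1e-7) < 1e-6

    def test_full_recovery_limit(self):
        # TR R1 >> 1: signal approaches PD sin(alpha)
        s = spoiled_gre_signal(2.0, 1.0, 50.0, 18.0)
        assert s == pytest.approx(2.0 * math.sin(math.radians(18.0)), rel=1e-9)

    def test_closed_form_value(self):
        e = math.exp(-0.016 * 1.0)
        a = math.radians(18.0)
        expected = math.sin(a) * (1 - e) / (1 - e * math.cos(a))
        assert spoiled_gre_signal(1.0, 1.0, 0.016, 18.0) == pytest.approx(
            expected, rel=1e-14)


class TestProtocolTypes:
    def test_tr_must_exceed_pulse_duration(self):
        pulse = MTPulse(1500.0, 500.0, 7.68e-3)
        with pytest.raises(ValueError):
            AcquisitionProtocol(0.005, 8.0, mt_pulse=pulse)

    def test_constraint_validation(self):
        with pytest.raises(ValueError):
            TwoPoolConstraints(cross_relaxation_rate=-1.0)
        with pytest.raises(ValueError):
            TwoPoolConstraints(r1t2_free=1.5)
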