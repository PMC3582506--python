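"""FRAP forward models: closed forms, Laplace inversion, PDE cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dsbdyn.frap_models import (
    BindingRates,
    BleachGeometry,
    DiffusionParams,
    ParameterDomainError,
    diffusion_timescale,
    effective_diffusion_coefficient,
    global_binding_frap,
    local_binding_frap,
    soumpasis_frap,
    stehfest_invert,
)

from pde_oracle import local_binding_frap_fd

GEOM = BleachGeometry(spot_radius_um=1.5, nucleus_radius_um=9.4)
D12 = DiffusionParams(12.0)

# frozen from a 50-digit evaluation of exp(-2) (I0(2) + I1(2))
SOUMPASIS_AT_TAU_D = 0.52377761180260874


class TestSoumpasis:
    def test_value_at_diffusion_time(self):
        tau = diffusion_timescale(D12, GEOM)
        assert soumpasis_frap(tau, D12, GEOM) == pytest.approx(SOUMPASIS_AT_TAU_D, abs=1e-12)

    def test_full_recovery_limit(self):
        assert soumpasis_frap(1e9, D12, GEOM) == pytest.approx(1.0, abs=1e-6)

    def test_curve_depends_only_on_scaled_time(self):
        # D=12 curve equals D=3 curve with the time axis stretched 4x
        t = np.linspace(0.01, 2.0, 40)
        f_fast = soumpasis_frap(t, DiffusionParams(12.0), GEOM)
        f_slow = soumpasis_frap(4.0 * t, DiffusionParams(3.0), GEOM)
        np.testing.assert_allclose(f_fast, f_slow, atol=1e-14)

    def test_incomplete_bleach_rescales_to_floor(self):
        geom = BleachGeometry(1.5, 9.4, bleach_depth=0.3)
        t = np.linspace(0.01, 5.0, 20)
        full = soumpasis_frap(t, D12, GEOM)
        partial = soumpasis_frap(t, D12, geom)
        np.testing.assert_allclose(partial, 0.3 + 0.7 * full, atol=1e-14)
        assert soumpasis_frap(0.0, D12, geom) == pytest.approx(0.3)

    def test_monotone_nondecreasing(self):
        t = np.linspace(1e-4, 10, 500)
        f = soumpasis_frap(t, D12, GEOM)
        assert np.all(np.diff(f) >= 0)

    @pytest.mark.parametrize("bad_t", [-1.0, np.nan, np.inf])
    def test_rejects_invalid_time(self, bad_t):
        with pytest.raises(ParameterDomainError):
            soumpasis_frap(bad_t, D12, GEOM)

    def test_rejects_invalid_diffusion(self):
        with pytest.raises(ParameterDomainError):
            DiffusionParams(-1.0)


class TestStehfest:
    # (transform, exact inverse, t, tolerance) — the 1/sqrt(p) pair probes
    # the method's known accuracy limit for weak singularities
    PAIRS = [
        (lambda p: 1.0 / p, lambda t: 1.0, 2.0, 1e-8),
        (lambda p: 1.0 / p**2, lambda t: t, 3.0, 1e-6),
        (lambda p: 1.0 / (p + 1.0), lambda t: np.exp(-t), 1.0, 1e-4),
        (lambda p: 1.0 / (p * (p + 0.5)), lambda t: (1 - np.exp(-0.5 * t)) / 0.5, 2.0, 1e-4),
        (lambda p: 1.0 / np.sqrt(p), lambda t: 1.0 / np.sqrt(np.pi * t), 1.5, 2e-3),
    ]

    @pytest.mark.parametrize("fbar,inverse,t,tol", PAIRS)
    def test_known_transform_pairs(self, fbar, inverse, t, tol):
        exact = inverse(t)
        approx = stehfest_invert(fbar, t)
        assert abs(approx - exact) <= tol * max(1.0, abs(exact))

    def test_odd_term_count_rejected(self):
        with pytest.raises(ParameterDomainError):
            stehfest_invert(lambda p: 1.0 / p, 1.0, n_terms=7)

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_constant_transform_everywhere(self, t):
        assert stehfest_invert(lambda p: 1.0 / p, t) == pytest.approx(1.0, abs=1e-7)


class TestGlobalBinding:
    def test_no_binding_reduces_to_pure_diffusion(self):
        t = np.linspace(0.01, 1.0, 50)
        g = global_binding_frap(t, D12, BindingRates(0.0, 1.0), GEOM)
        s = soumpasis_frap(t, D12, GEOM)
        np.testing.assert_allclose(g, s, atol=1e-4)

    def test_fast_exchange_is_effective_diffusion(self):
        # kon*/koff = 9 with koff >> 1/tau_D slows diffusion tenfold
        tau = diffusion_timescale(D12, GEOM)
        koff = 1e3 / tau
        rates = BindingRates(9.0 * koff, koff)
        t = np.linspace(0.01, 5 * tau, 60)
        g = global_binding_frap(t, D12, rates, GEOM)
        s = soumpasis_frap(t, effective_diffusion_coefficient(D12, rates), GEOM)
        np.testing.assert_allclose(g, s, atol=2e-2)

    def test_full_exchange_at_long_times(self):
        rates = BindingRates(0.01, 0.02)
        out = global_binding_frap(np.array([1e5]), D12, rates, GEOM)
        assert out[-1] == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("kon,koff", [(74e-5, 193e-5), (0.1, 0.01), (5.0, 0.5)])
    def test_bounded_and_nondecreasing(self, kon, koff):
        t = np.geomspace(0.05, 10 / koff, 80)
        g = global_binding_frap(t, DiffusionParams(0.029), BindingRates(kon, koff), GEOM)
        assert np.all(g >= -1e-6) and np.all(g <= 1 + 1e-6)
        assert np.all(np.diff(g) >= -1e-3)


class TestLocalBinding:
    def test_no_binding_matches_pure_diffusion(self):
        # bounded-domain solution, pre-bleach-normalized on both sides
        geom = BleachGeometry(1.5, 4.5)  # R_n = 3 w
        tau = diffusion_timescale(D12, geom)
        t = np.linspace(0.01, 5 * tau, 50)
        loc = local_binding_frap(t, D12, BindingRates(0.0, 1.0), geom,
                                 pool_correction=False)
        s = soumpasis_frap(t, D12, GEOM)
        np.testing.assert_allclose(loc, s, atol=2e-2)

    def test_full_recovery_at_long_times(self):
        rates = BindingRates(0.5, 0.05)
        out = local_binding_frap(np.array([1e6]), D12, rates, GEOM)
        assert out[-1] == pytest.approx(1.0, abs=1e-3)

    def test_recovery_slows_with_association_rate(self):
        koff = 0.05
        t = np.array([1.0, 5.0, 20.0])
        prev = None
        for factor in [0.0, 0.1, 1.0, 10.0]:
            cur = local_binding_frap(t, DiffusionParams(1.0),
                                     BindingRates(factor * koff, koff), GEOM,
                                     pool_correction=False)
            if prev is not None:
                assert np.all(cur <= prev + 1e-9)
            prev = cur

    @pytest.mark.parametrize("kon", [0.05, 0.5, 5.0])
    @pytest.mark.parametrize("koff", [0.05, 0.5, 5.0])
    def test_matches_finite_difference_oracle(self, kon, koff):
        # independent Crank-Nicolson PDE solver, same two-region problem
        w, rn, d = 1.5, 4.5, 2.0
        t = np.linspace(0.05, 10.0, 25)
        geom = BleachGeometry(w, rn)
        lap = local_binding_frap(t, DiffusionParams(d), BindingRates(kon, koff),
                                 geom, pool_correction=False)
        fd = local_binding_frap_fd(t, d, kon, koff, w, rn)
        np.testing.assert_allclose(lap, fd, atol=2e-2)

    def test_bounded_values(self):
        t = np.geomspace(0.1, 5e4, 60)
        out = local_binding_frap(t, DiffusionParams(0.029),
                                 BindingRates(587e-3, 425e-5), GEOM)
        assert np.all(out >= -1e-6) and np.all(out <= 1 + 1e-6)
        assert np.all(np.diff(out) >= -1e-3)


class TestEffectiveDiffusion:
    @pytest.mark.parametrize("kon_over_koff,expected_factor",
                             [(0.0, 1.0), (1.0, 0.5), (9.0, 0.1)])
    def test_retardation_factor(self, kon_over_koff, expected_factor):
        rates = BindingRates(kon_over_koff * 2.0, 2.0)
        deff = effective_diffusion_coefficient(D12, rates)
        assert deff.D == pytest.approx(12.0 * expected_factor)
        assert deff.D <= D12.D
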