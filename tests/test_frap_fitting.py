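"""Normalization, diffusion/binding estimation and mobility arithmetic."""

import itertools

import numpy as np
import pytest

from dsbdyn.frap_fitting import (
    GLOBAL_BINDING,
    LOCAL_BINDING,
    DataQualityError,
    FrapCurve,
    double_normalize,
    fit_binding_constants,
    fit_effective_diffusion,
    round_sig,
    scaled_diffusion_estimate,
    traversal_time,
)
from dsbdyn.frap_models import (
    BindingRates,
    BleachGeometry,
    DiffusionParams,
    global_binding_frap,
    soumpasis_frap,
)

GEOM = BleachGeometry(spot_radius_um=1.5, nucleus_radius_um=9.4)


def _times(n_pre=3, dt=0.1, n_post=100):
    return np.concatenate([-dt * np.arange(n_pre, 0, -1), dt * np.arange(1, n_post + 1)])


class TestDoubleNormalize:
    def test_constant_signals_normalize_to_one(self):
        t = _times()
        c = double_normalize(t, np.full(t.size, 7.0), np.full(t.size, 3.0),
                             n_prebleach=3)
        np.testing.assert_allclose(c.intensities, 1.0)

    def test_acquisition_bleaching_cancels(self):
        t = _times()
        lam = 0.03
        roi = 0.5 * np.exp(-lam * (t - t[0]))
        whole = np.exp(-lam * (t - t[0]))
        c = double_normalize(t, roi, whole, n_prebleach=3)
        np.testing.assert_allclose(c.intensities, 1.0, atol=1e-12)

    def test_plain_arithmetic(self):
        t = _times(n_pre=2, n_post=10)
        roi = np.concatenate([[200.0, 200.0], np.full(10, 80.0)])
        whole = np.full(t.size, 500.0)
        c = double_normalize(t, roi, whole, n_prebleach=2)
        np.testing.assert_allclose(c.intensities[2:], 0.4)

    def test_idempotent_on_normalized_curve(self):
        t = _times()
        model = np.concatenate([np.ones(3), soumpasis_frap(t[3:], DiffusionParams(2.0), GEOM)])
        once = double_normalize(t, model, np.ones(t.size), n_prebleach=3)
        twice = double_normalize(t, once.intensities, np.ones(t.size), n_prebleach=3)
        np.testing.assert_allclose(once.intensities, twice.intensities, atol=1e-12)
        assert abs(once.intensities[:3].mean() - 1.0) < 1e-9

    def test_names_offending_frame(self):
        t = _times(n_pre=2, n_post=10)
        whole = np.full(t.size, 10.0)
        whole[5] = -1.0
        with pytest.raises(DataQualityError, match="frame 5"):
            double_normalize(t, np.full(t.size, 5.0), whole, np.zeros(t.size),
                             n_prebleach=2)


class TestEffectiveDiffusionFit:
    @pytest.mark.parametrize("d_true,dt,n", [(12.0, 0.1, 100), (0.029, 5.0, 200)])
    def test_noise_free_self_consistency(self, d_true, dt, n):
        t = dt * np.arange(1, n + 1)
        y = soumpasis_frap(t, DiffusionParams(d_true), GEOM)
        res = fit_effective_diffusion(FrapCurve(t, y), GEOM, d_start=1.0)
        assert res.success
        assert res.D_eff.D == pytest.approx(d_true, rel=0.01)

    def test_time_and_geometry_scale_invariance(self):
        # stretching t by k and w^2 by k leaves tau_D and hence D unchanged
        k = 9.0
        t = 0.1 * np.arange(1, 80)
        y = soumpasis_frap(t, DiffusionParams(3.0), GEOM)
        geom_k = BleachGeometry(GEOM.spot_radius_um * np.sqrt(k), 60.0)
        yk = soumpasis_frap(k * t, DiffusionParams(3.0), geom_k)
        d1 = fit_effective_diffusion(FrapCurve(t, y), GEOM).D_eff.D
        d2 = fit_effective_diffusion(FrapCurve(k * t, yk), geom_k).D_eff.D
        assert d1 == pytest.approx(d2, rel=1e-6)

    def test_too_few_frames_flagged(self):
        t = 0.1 * np.arange(1, 6)
        y = soumpasis_frap(t, DiffusionParams(1.0), GEOM)
        res = fit_effective_diffusion(FrapCurve(t, y), GEOM)
        assert not res.success


REDUCED_DECADES = tuple(10.0**e for e in (-6, -3, 0, 3, 6))


class TestBindingConstantFit:
    def test_nested_no_binding_limit(self):
        # pure-diffusion data: binding model collapses onto kon* ~ 0
        t = np.geomspace(0.05, 20.0, 80)
        d = DiffusionParams(0.5)
        y = soumpasis_frap(t, d, GEOM)
        res = fit_binding_constants(FrapCurve(t, y), GLOBAL_BINDING, d, GEOM,
                                    start_decades=REDUCED_DECADES)
        assert res.success
        assert res.rates.kon_star <= 1e-6
        assert res.sse < 1e-6

    def test_decade_grid_matches_dense_random_start_oracle(self):
        # the printed-constant and two harder synthetic cases
        cases = [
            (74e-5, 193e-5, 0.029),
            (0.05, 0.005, 0.1),
            (2.0, 0.2, 1.0),
        ]
        rng = np.random.default_rng(42)
        for kon, koff, d in cases:
            t = np.geomspace(0.1, 8.0 / koff, 90)
            dparams = DiffusionParams(d)
            y = global_binding_frap(t, dparams, BindingRates(kon, koff), GEOM)
            curve = FrapCurve(t, y)
            grid = fit_binding_constants(curve, GLOBAL_BINDING, dparams, GEOM,
                                         start_decades=REDUCED_DECADES)
            # denser random-start oracle over the same log-space box
            from scipy.optimize import least_squares

            def residuals(x):
                r = BindingRates(10.0 ** x[0], 10.0 ** x[1])
                return global_binding_frap(t, dparams, r, GEOM) - y

            best = np.inf
            for _ in range(150):
                x0 = rng.uniform(-6, 6, size=2)
                r = least_squares(residuals, x0, bounds=([-8, -8], [8, 8]),
                                  max_nfev=60)
                best = min(best, 2.0 * r.cost)
            assert grid.sse <= best + 1e-12

    def test_noisy_recovery_rate(self):
        # 1% noise; both constants within 15% in >= 90% of 50 replicates
        kon, koff, d = 0.02, 0.002, 0.029
        t = np.geomspace(0.5, 5.0 / koff, 70)
        dparams = DiffusionParams(d)
        clean = global_binding_frap(t, dparams, BindingRates(kon, koff), GEOM)
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            y = clean * (1.0 + 0.01 * rng.standard_normal(t.size))
            res = fit_binding_constants(FrapCurve(t, y), GLOBAL_BINDING,
                                        dparams, GEOM,
                                        start_decades=REDUCED_DECADES)
            if (res.success
                    and abs(res.rates.kon_star - kon) / kon < 0.15
                    and abs(res.rates.koff - koff) / koff < 0.15):
                hits += 1
        assert hits >= 45

    def test_reported_optimum_not_worse_than_any_start(self):
        t = np.geomspace(0.1, 500.0, 60)
        d = DiffusionParams(0.1)
        y = global_binding_frap(t, d, BindingRates(0.05, 0.01), GEOM)
        res = fit_binding_constants(FrapCurve(t, y), GLOBAL_BINDING, d, GEOM,
                                    start_decades=REDUCED_DECADES)
        assert res.sse <= min(res.all_start_sse.values()) + 1e-12
        assert res.start_values_tried == len(REDUCED_DECADES) ** 2


class TestMobilityArithmetic:
    @pytest.mark.parametrize("mass,expected", [(27, 12.0), (137, 7.0), (257, 5.7)])
    def test_cube_root_mass_scaling(self, mass, expected):
        d = scaled_diffusion_estimate(DiffusionParams(12.0), 27.0, mass)
        assert round_sig(d.D, 2) == pytest.approx(expected)

    @pytest.mark.parametrize("d,expected,tol", [
        (12.0, 0.83, 0.005),   # free GFP crosses the nucleus in under a second
        (0.25, 40.0, 1.0),     # NBS1, ~40 s
        (0.029, 340.0, 5.0),   # MDC1, ~340 s
    ])
    def test_nuclear_traversal_times(self, d, expected, tol):
        assert traversal_time(6.3, DiffusionParams(d)) == pytest.approx(expected, abs=tol)

    def test_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError):
            scaled_diffusion_estimate(DiffusionParams(12.0), 0.0, 137.0)
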