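"""Estimation pipeline: peak detection, secant moduli, residuals, full fit.

Residual statistics are cross-checked against a deliberately naive
loop-based oracle; the full fit is checked on noiseless model-generated
curves, where the peak quantities are recovered exactly and the secant
elastic modulus converges to the plug-in value q/x_q — the estimator's
known self-consistency limit, strictly below the generating modulus.
"""

import math

import numpy as np
import pytest

from rootmech import (
    DegenerateCurveError,
    GeneratorConfig,
    SamplingError,
    StressStrainCurve,
    critical_point,
    fit_curve,
    generate_curve,
    normalize_curve,
    peak_point,
    peak_secant_modulus,
    plug_in_modulus_ratio,
    residual_statistics,
    secant_modulus_at_fraction,
    stress_ratio,
)


def brute_force_residuals(x, y, E):
    """Independent oracle: plain-Python residual mean-|.| and variance."""
    r = [yi - stress_ratio(xi, E) for xi, yi in zip(x, y)]
    n = len(r)
    mean_abs = sum(abs(v) for v in r) / n
    mean = sum(r) / n
    var = sum((v - mean) ** 2 for v in r) / (n - 1)
    return mean_abs, var


class TestPeakPoint:
    def test_monotone_curve(self):
        c = StressStrainCurve([0, 0.01, 0.02], [0, 10, 20])
        assert peak_point(c) == (0.02, 20.0)
        assert peak_secant_modulus(c) == pytest.approx(1000.0)

    def test_first_attainment_tie_break(self):
        c = StressStrainCurve([0, 0.01, 0.02, 0.03], [0, 10, 20, 20])
        assert peak_point(c) == (0.02, 20.0)
        # plateau tail does not change the peak secant modulus
        assert peak_secant_modulus(c) == pytest.approx(1000.0)

    def test_noiseless_round_trip(self, noiseless_curve):
        curve, params = noiseless_curve
        eps_p, sigma_p = peak_point(curve)
        assert eps_p == params.eps_p
        assert sigma_p == params.sigma_p

    def test_all_zero_stress_degenerate(self):
        c = StressStrainCurve([0, 0.01, 0.02], [0, 0, 0])
        with pytest.raises(DegenerateCurveError):
            peak_point(c)


class TestSecantModulus:
    def test_linear_curve_any_fraction(self):
        eps = np.linspace(0, 0.1, 50)
        c = StressStrainCurve(eps, 100.0 * eps)
        for q in (0.2, 0.4, 0.8):
            assert secant_modulus_at_fraction(c, q) == pytest.approx(100.0)

    def test_interpolated_crossing(self):
        # q*sigma_p = 40 falls midway between (0.003, 30) and (0.005, 50)
        c = StressStrainCurve([0.0, 0.003, 0.005, 0.01], [0.0, 30.0, 50.0, 100.0])
        assert secant_modulus_at_fraction(c, 0.4) == pytest.approx(10000.0)

    def test_plug_in_value_on_model_curve(self):
        # Ep = 1, sigma_p = 1, eps_p = 1, E_true = 2 on a dense grid:
        # estimate -> 0.4/x_q = 0.4/(1 - sqrt(0.6))
        x = np.linspace(0, 1, 20001)
        c = StressStrainCurve(x, stress_ratio(x, 2.0))
        expected = 0.4 / (1.0 - math.sqrt(0.6))
        assert secant_modulus_at_fraction(c, 0.4) == pytest.approx(
            expected, abs=1e-6
        )

    def test_unbracketed_crossing_errors(self):
        c = StressStrainCurve([0.01, 0.02, 0.03], [50.0, 80.0, 100.0])
        with pytest.raises(SamplingError):
            secant_modulus_at_fraction(c, 0.4)


class TestNormalize:
    def test_endpoints_and_truncation(self):
        c = StressStrainCurve(
            [0, 0.05, 0.1, 0.12, 0.14], [0, 18, 30, 29, 29.5]
        )
        x, y = normalize_curve(c)
        assert x[0] == 0.0 and y[0] == 0.0
        assert x[-1] == 1.0 and y[-1] == 1.0
        assert len(x) == 3  # necking tail dropped


class TestResidualStatistics:
    def test_exact_model_points(self, noiseless_curve):
        curve, params = noiseless_curve
        x, y = normalize_curve(curve)
        mean_abs, var = residual_statistics(x, y, params.E)
        assert mean_abs == 0.0  # exact: power-of-two peak stress
        assert var == 0.0

    def test_constant_offset(self):
        x = np.linspace(0.0, 1.0, 30)
        y = stress_ratio(x, 1.8) + 0.05
        mean_abs, var = residual_statistics(x, y, 1.8)
        assert mean_abs == pytest.approx(0.05, abs=1e-12)
        assert var == pytest.approx(0.0, abs=1e-15)

    def test_matches_brute_force_oracle(self, presets):
        cfg = GeneratorConfig(
            params=presets["Larix_gmelinii_2.99"], n_points=120,
            noise_sd=0.02, seed=424242,
        )
        curve, params = generate_curve(cfg)
        x, y = normalize_curve(curve)
        got = residual_statistics(x, y, params.E)
        want = brute_force_residuals(x, y, params.E)
        assert got[0] == pytest.approx(want[0], abs=1e-15)
        assert got[1] == pytest.approx(want[1], abs=1e-15)

    def test_ddof_option(self):
        x = np.linspace(0.0, 1.0, 10)
        y = stress_ratio(x, 2.0) + np.linspace(-0.01, 0.01, 10)
        _, v1 = residual_statistics(x, y, 2.0, ddof=1)
        _, v0 = residual_statistics(x, y, 2.0, ddof=0)
        assert v1 == pytest.approx(v0 * 10 / 9, rel=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            residual_statistics([0.5], [0.6], 2.0)


class TestFitCurve:
    def test_noiseless_recovery(self, presets):
        for name in ("Pinus_tabulaeformis_2.00", "Quercus_mongolica_4.39"):
            params = presets[name]
            cfg = GeneratorConfig(params=params, n_points=4001, noise_sd=0.0, seed=0)
            curve, _ = generate_curve(cfg)
            fit = fit_curve(curve)
            assert fit.valid
            assert fit.sigma_p == params.sigma_p
            assert fit.Ep == pytest.approx(params.Ep, rel=1e-12)
            expected_E = plug_in_modulus_ratio(params.E, 0.4)
            assert fit.E == pytest.approx(expected_E, abs=1e-6)
            assert fit.x_e == pytest.approx(critical_point(fit.E, 0.4), abs=1e-9)
            # data-based critical point equals the model one on exact data
            assert fit.x_e_data == pytest.approx(
                critical_point(params.E, 0.4), abs=1e-5
            )

    def test_published_modulus_through_pipeline(self):
        # a pipeline whose secant step lands on E0=107.12 with Ep=61.46
        # must report E at the published 5-decimal value
        E = 107.12 / 61.46
        assert round(E, 5) == 1.74292

    def test_linear_curve_flagged_invalid(self):
        eps = np.linspace(0, 0.1, 60)
        c = StressStrainCurve(eps, 250.0 * eps)
        fit = fit_curve(c)
        assert not fit.valid
        assert fit.params is None
        assert fit.E == pytest.approx(1.0, rel=1e-9)
        assert math.isnan(fit.x_e)
        assert math.isnan(fit.mean_abs_residual)
        # diagnostics retained
        assert fit.E0 == pytest.approx(250.0)
        assert fit.Ep == pytest.approx(250.0)

    def test_necking_tail_changes_nothing(self, presets):
        params = presets["Betula_platyphylla_2.41"]
        base = GeneratorConfig(params=params, n_points=150, noise_sd=0.01, seed=7)
        neck = GeneratorConfig(
            params=params, n_points=150, noise_sd=0.01, seed=7,
            post_peak_mode="necking_plateau", tail_fraction=0.3,
        )
        f0 = fit_curve(generate_curve(base)[0])
        f1 = fit_curve(generate_curve(neck)[0])
        for attr in ("sigma_p", "eps_p", "E0", "Ep", "E", "x_e",
                     "mean_abs_residual", "residual_variance",
                     "n_points_used"):
            assert getattr(f0, attr) == getattr(f1, attr), attr


class TestPlugInModulusRatio:
    def test_quadratic_closed_form(self):
        expected = 0.4 / (1.0 - math.sqrt(0.6))
        assert plug_in_modulus_ratio(2.0, 0.4) == pytest.approx(
            expected, abs=1e-6
        )

    def test_against_bisection_free_oracle(self):
        # independent route: solve y(x)=q by dense-grid refinement
        E, q = 1.5, 0.4
        x = np.linspace(0, 1, 2_000_001)
        y = stress_ratio(x, E)
        xq = float(np.interp(q, y, x))
        assert plug_in_modulus_ratio(E, q) == pytest.approx(q / xq, rel=1e-9)

    def test_always_below_truth_and_limit(self):
        # start at E=1.1: the analytic gap E - q/x_q shrinks like
        # (E-1)*x_q^n and falls below the inversion tolerance as E -> 1+
        for E in np.linspace(1.1, 10.0, 25):
            assert plug_in_modulus_ratio(E, 0.4) < E
        # q -> 0: secant tends to the tangent at the origin
        assert plug_in_modulus_ratio(3.0, 1e-6) == pytest.approx(3.0, rel=1e-3)

    def test_noise_consistency(self, presets):
        params = presets["Pinus_tabulaeformis_3.06"]
        target = plug_in_modulus_ratio(params.E, 0.4)
        errs = []
        for noise in (0.05, 0.01, 0.001):
            reps = []
            for r in range(30):
                cfg = GeneratorConfig(
                    params=params, n_points=400, noise_sd=noise, seed=900 + r
                )
                reps.append(fit_curve(generate_curve(cfg)[0]).E)
            errs.append(abs(np.mean(reps) - target))
        assert errs[2] < errs[0]  # estimates tighten toward the plug-in value
        assert errs[2] < 5e-3
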