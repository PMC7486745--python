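import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

from spincascade.kinetics import (CascadeParams, cascade_populations,
                                  compare_models, emg_response, fit_trace,
                                  _pump_cumulative)
from spincascade.spectra_core import KineticTrace
from spincascade.synthetic_data import synth_kinetic_trace, weights_for_biexp

_G2S = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def quad_convolution(t, t0, irf_fwhm, tau):
    """Adaptive-quadrature oracle for the Gaussian x exponential convolution."""
    sig = irf_fwhm * _G2S

    def integrand(u):
        return (np.exp(-u / tau) * np.exp(-((t - t0 - u) / sig) ** 2 / 2.0)
                / (sig * np.sqrt(2.0 * np.pi)))

    upper = max(t - t0 + 12 * sig, 20 * tau)
    # piecewise around the (possibly very narrow) Gaussian peak at u = t - t0
    edges = sorted({0.0, upper} | {
        np.clip(t - t0 + k * sig, 0.0, upper) for k in (-8.0, 8.0)})
    val = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi > lo:
            part, _ = quad(integrand, lo, hi, limit=500,
                           epsabs=1e-13, epsrel=1e-12)
            val += part
    return val


class TestEMGResponse:
    def test_zero_irf_limit_is_causal_exponential(self):
        assert emg_response(np.array([1.61]), 1.0, 0.0, 0.61)[0] == \
            pytest.approx(np.exp(-1.0), abs=1e-15)
        # vanishing-but-finite IRF approaches the same limit
        assert emg_response(np.array([1.61]), 1.0, 1e-8, 0.61)[0] == \
            pytest.approx(np.exp(-1.0), abs=1e-9)

    def test_causality_before_the_pump(self):
        vals = emg_response(np.array([-2.0, -1.5]), 0.0, 0.14, 0.61)
        assert np.all(vals < 1e-12)

    @pytest.mark.parametrize("ratio", [0.01, 0.1, 1.0, 5.0, 10.0])
    def test_matches_quadrature_oracle(self, ratio):
        tau = 0.61
        irf = ratio * tau / _G2S  # sigma/tau = ratio
        for t in (-0.5, 0.0, 0.3, 2.0, 10.0):
            assert abs(emg_response(np.array([t]), 0.0, irf, tau)[0]
                       - quad_convolution(t, 0.0, irf, tau)) < 1e-8

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            emg_response([0.0], 0.0, 0.1, -1.0)
        with pytest.raises(ValueError):
            emg_response([0.0], 0.0, -0.1, 1.0)


class TestCascadePopulations:
    def test_absorbing_limit_is_pump_cumulative(self):
        p = CascadeParams(tau1_ps=0.61, tau3_ps=1e7, f_exc=0.4)
        t = np.linspace(5.0, 40.0, 20)  # well past the IS decay
        _, n_hs = cascade_populations(t, p)
        expect = p.f_exc * _pump_cumulative(t, p.t0_ps, p.irf_fwhm_ps)
        np.testing.assert_allclose(n_hs, expect, atol=1e-3)

    @pytest.mark.parametrize("tau1,tau3", [(0.61, 8.7), (1.0, 1.2),
                                           (3.0, 0.5)])
    def test_hs_peaks_after_is(self, tau1, tau3):
        p = CascadeParams(tau1_ps=tau1, tau3_ps=tau3)
        t = np.linspace(-1.0, 30.0, 3000)
        n_is, n_hs = cascade_populations(t, p)
        assert t[np.argmax(n_hs)] > t[np.argmax(n_is)]

    def test_degenerate_lifetimes_match_ode_oracle(self):
        p = CascadeParams(tau1_ps=2.0, tau3_ps=2.0)
        sig = p.irf_fwhm_ps * _G2S

        def rhs(t, y):
            pump = (p.f_exc * np.exp(-(t / sig) ** 2 / 2)
                    / (sig * np.sqrt(2 * np.pi)))
            return [pump - y[0] / 2.0, y[0] / 2.0 - y[1] / 2.0]

        ts = np.linspace(-1.0, 15.0, 30)
        sol = solve_ivp(rhs, (-1.5, 15.0), [0.0, 0.0], t_eval=ts,
                        rtol=1e-10, atol=1e-13)
        n_is, n_hs = cascade_populations(ts, p)
        assert np.max(np.abs(sol.y[1] - n_hs)) < 1e-6
        assert np.max(np.abs(sol.y[0] - n_is)) < 1e-6

    def test_degenerate_branch_is_continuous(self):
        # approaching the degenerate point from outside matches the
        # analytic-limit branch
        t = np.linspace(-0.5, 10.0, 200)
        exact = cascade_populations(t, CascadeParams(tau1_ps=2.0,
                                                     tau3_ps=2.0))[1]
        near = cascade_populations(t, CascadeParams(tau1_ps=2.0,
                                                    tau3_ps=2.0 * (1 + 1e-5)
                                                    ))[1]
        assert np.max(np.abs(exact - near)) < 1e-4


def _noisy_trace(params, a1=0.7, a3=0.3, noise=0.05, seed=0):
    return synth_kinetic_trace("xanes_amplitude", params,
                               weights=weights_for_biexp(a1, a3, params),
                               noise_level=noise, seed=seed)


class TestFitTrace:
    def test_noiseless_round_trip(self, xanes_truth):
        tr = _noisy_trace(xanes_truth, noise=0.0)
        fit = fit_trace(tr, 2, n_boot=0)
        (a1, tau1), (a3, tau3) = fit.components
        for got, want in [(a1, 0.7), (tau1, 0.61), (a3, 0.3), (tau3, 8.7),
                          (fit.irf_fwhm_ps, 0.14)]:
            assert abs(got / want - 1) < 1e-6
        assert abs(fit.t0_ps) < 1e-6
        assert fit.converged

    def test_fix_irf_is_honored(self, xanes_truth):
        tr = _noisy_trace(xanes_truth, seed=3)
        fit = fit_trace(tr, 2, fix_irf=0.14, n_boot=0)
        assert fit.irf_fwhm_ps == 0.14
        assert "irf_fwhm" not in fit.param_sigmas

    def test_affine_rescaling_leaves_shape_parameters(self, xanes_truth):
        tr = _noisy_trace(xanes_truth, seed=5)
        fit0 = fit_trace(tr, 2, n_boot=0)
        scaled = KineticTrace(tr.delay_ps, 10.0 * tr.signal + 3.0,
                              sigma=10.0 * tr.sigma, label=tr.label)
        fit1 = fit_trace(scaled, 2, n_boot=0)
        for (a0, t0), (a1, t1) in zip(fit0.components, fit1.components):
            assert abs(t1 / t0 - 1) < 1e-6
            assert abs(a1 / a0 - 10.0) < 1e-5
        assert abs(fit1.baseline - (10.0 * fit0.baseline + 3.0)) < 1e-5
        assert abs(fit1.irf_fwhm_ps / fit0.irf_fwhm_ps - 1) < 1e-6

    def test_bootstrap_is_seeded_and_deterministic(self, xanes_truth):
        tr = _noisy_trace(xanes_truth, seed=11)
        a = fit_trace(tr, 2, n_boot=25, seed=4)
        b = fit_trace(tr, 2, n_boot=25, seed=4)
        assert a.ci68 == b.ci68
        lo, hi = a.ci68["tau1"]
        assert lo < a.components[0][1] < hi

    def test_monoexponential_data_flags_weak_second_component(self):
        p = CascadeParams(tau1_ps=5.0, tau3_ps=5.0 * (1 + 1e-9), f_exc=1.0)
        tr = synth_kinetic_trace("xanes_amplitude", p, weights=(1.0, 0.0),
                                 noise_level=0.03, seed=21)
        fit = fit_trace(tr, 2, n_boot=60, seed=0)
        rep = compare_models(tr, [fit])
        comps = rep.iloc[0]["components"]
        assert any(c["weak"] for c in comps)

    def test_zero_trace_rejected(self):
        t = np.linspace(-1, 10, 50)
        with pytest.raises(ValueError, match="zero"):
            fit_trace(KineticTrace(t, np.zeros_like(t)), 1, n_boot=0)

    def test_invalid_component_count_rejected(self, xanes_truth):
        tr = _noisy_trace(xanes_truth)
        with pytest.raises(ValueError):
            fit_trace(tr, 4)

    def test_short_tail_warns(self, xanes_truth):
        tr = synth_kinetic_trace(
            "xanes_amplitude", xanes_truth,
            weights=weights_for_biexp(0.7, 0.3, xanes_truth),
            delays=np.linspace(-1.0, 6.0, 60), noise_level=0.0)
        with pytest.warns(UserWarning, match="tail"):
            fit_trace(tr, 2, n_boot=0)


class TestCompareModels:
    def test_identical_fits_get_identical_scores(self, xanes_truth):
        tr = _noisy_trace(xanes_truth, seed=8)
        fit = fit_trace(tr, 2, n_boot=0)
        rep = compare_models(tr, [fit, fit])
        assert rep.loc[0, "aicc"] == rep.loc[1, "aicc"]
        assert rep.loc[0, "residual_rms"] == rep.loc[1, "residual_rms"]

    def test_biexponential_preferred_over_mono(self, xanes_truth):
        tr = _noisy_trace(xanes_truth, seed=9)
        f1 = fit_trace(tr, 1, n_boot=0)
        f2 = fit_trace(tr, 2, n_boot=0)
        rep = compare_models(tr, [f1, f2])
        assert rep.loc[0, "n_components"] == 2
        assert bool(rep.loc[rep.n_components == 1,
                            "unsupported_extra"].iloc[0]) is False

    def test_extra_component_marked_unsupported(self, xanes_truth):
        tr = _noisy_trace(xanes_truth, seed=10)
        f2 = fit_trace(tr, 2, n_boot=0)
        f3 = fit_trace(tr, 3, n_boot=0)
        rep = compare_models(tr, [f2, f3])
        row3 = rep[rep.n_components == 3].iloc[0]
        assert row3["unsupported_extra"] or row3["weak_components"]
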