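import numpy as np
import pytest
from scipy.integrate import solve_ivp

from spincascade.kinetics import CascadeParams
from spincascade.lineshape import numeric_fwhm
from spincascade.synthetic_data import (HS, IS, LS, SpinState,
                                        default_delays, default_xes_grid,
                                        simulate_populations,
                                        species_spectrum, synth_kinetic_trace,
                                        synth_timeseries, weights_for_biexp,
                                        _kalpha_lines, DEFAULT_LINE_MODEL)


class TestSpinState:
    def test_canonical_states(self):
        assert (LS.n_unpaired, IS.n_unpaired, HS.n_unpaired) == (1, 3, 5)
        assert all(s.two_S == s.n_unpaired for s in (LS, IS, HS))

    @pytest.mark.parametrize("args", [("XS", 1, 1), ("LS", 3, 3),
                                      ("HS", 5, 3)])
    def test_invalid_states_rejected(self, args):
        with pytest.raises(ValueError):
            SpinState(*args)


class TestSpeciesSpectrum:
    def test_kalpha_doublet_peak_positions(self):
        grid = np.arange(6380.0, 6420.01, 0.01)
        sp = species_spectrum("kalpha", LS, grid)
        e, y = grid, sp.intensity
        main = e[np.argmax(y)]
        low = e[(e < 6398)][np.argmax(y[e < 6398])]
        assert abs(main - 6404.0) < 0.05
        assert abs(low - 6391.0) < 0.05

    def test_kalpha2_to_kalpha1_peak_ratio_near_half(self, species_ls):
        e, y = species_ls.energy_ev, species_ls.intensity
        p1 = y[np.argmin(np.abs(e - 6404.0))]
        p2 = y[np.argmin(np.abs(e - 6391.0))]
        assert abs(p2 / p1 - 0.5) < 0.05

    def test_fwhm_spin_ordering(self):
        widths = {}
        for st in (LS, IS, HS):
            (line1, _), _ = _kalpha_lines(st, DEFAULT_LINE_MODEL)
            widths[st.name] = numeric_fwhm(line1)
        assert widths["LS"] < widths["IS"]
        # saturation beyond S = 3/2: IS and HS widths coincide
        assert widths["IS"] <= widths["HS"] + 1e-9
        assert abs(widths["HS"] - widths["LS"] - 0.7) < 1e-6

    def test_kbeta_spin_signature_signs(self, kbeta_grid):
        ls = species_spectrum("kbeta", LS, kbeta_grid)
        hs = species_spectrum("kbeta", HS, kbeta_grid)
        d = hs.intensity - ls.intensity
        at = lambda e0: d[np.argmin(np.abs(kbeta_grid - e0))]
        assert at(7058.0) < 0   # mainline loses intensity
        assert at(7043.0) > 0   # sideband gains

    def test_total_emission_is_conserved_across_states(self, kalpha_grid):
        areas = [np.trapezoid(species_spectrum("kalpha", s, kalpha_grid)
                              .intensity, kalpha_grid) for s in (LS, IS, HS)]
        np.testing.assert_allclose(areas, areas[0], rtol=1e-12)

    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            species_spectrum("lalpha", LS)

    def test_narrow_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            species_spectrum("kalpha", LS, np.arange(6398.0, 6410.0, 0.2))


class TestPopulations:
    def test_pre_pump_and_full_recovery(self, xanes_truth):
        df = simulate_populations(xanes_truth, [-2.0, 500.0])
        early, late = df.iloc[0], df.iloc[1]
        assert abs(early.n_is) < 1e-12 and abs(early.n_hs) < 1e-12
        assert abs(early.n_gs - 1.0) < 1e-12
        assert abs(late.n_is) < 1e-9 and abs(late.n_hs) < 1e-9
        assert abs(late.n_gs - 1.0) < 1e-9

    @pytest.mark.parametrize("tau1,tau3", [(0.61, 8.7), (0.5, 0.5),
                                           (2.0, 0.3)])
    def test_matches_runge_kutta_oracle(self, tau1, tau3):
        p = CascadeParams(t0_ps=0.0, irf_fwhm_ps=0.14, tau1_ps=tau1,
                          tau3_ps=tau3, f_exc=0.3)
        sig = p.irf_fwhm_ps / (2 * np.sqrt(2 * np.log(2)))

        def rhs(t, y):
            pump = (p.f_exc * np.exp(-((t - p.t0_ps) / sig) ** 2 / 2)
                    / (sig * np.sqrt(2 * np.pi)))
            return [pump - y[0] / tau1, y[0] / tau1 - y[1] / tau3]

        ts = np.linspace(-1.0, 15.0, 40)
        sol = solve_ivp(rhs, (-1.5, 15.0), [0.0, 0.0], t_eval=ts,
                        rtol=1e-10, atol=1e-13)
        df = simulate_populations(p, ts)
        assert np.max(np.abs(sol.y[0] - df.n_is)) < 1e-6
        assert np.max(np.abs(sol.y[1] - df.n_hs)) < 1e-6

    def test_excited_fraction_conserved(self, xanes_truth):
        # n_is + n_hs + recovered ground == f_exc * pump cumulative,
        # with the recovered fraction obtained by integrating the HS decay
        from spincascade.kinetics import _pump_cumulative, cascade_populations
        p = xanes_truth
        ts = np.linspace(-1.0, 60.0, 400_000)
        n_is, n_hs = cascade_populations(ts, p)
        recovered = np.concatenate(
            [[0.0], np.cumsum(0.5 * (n_hs[1:] + n_hs[:-1])
                              * np.diff(ts)) / p.tau3_ps])
        lhs = n_is + n_hs + recovered
        rhs = p.f_exc * _pump_cumulative(ts, p.t0_ps, p.irf_fwhm_ps)
        assert np.max(np.abs(lhs - rhs)) < 1e-6  # limited by the quadrature


class TestTimeseries:
    def test_noiseless_transient_is_population_weighted_difference(
            self, xanes_truth, kalpha_grid):
        off, on = synth_timeseries("kalpha", xanes_truth, delays=[0.2],
                                   noise_level=0.0)[0]
        df = simulate_populations(xanes_truth, [0.2]).iloc[0]
        spec = {s.name: species_spectrum("kalpha", s, kalpha_grid).intensity
                for s in (LS, IS, HS)}
        expect = (df.n_is * (spec["IS"] - spec["LS"])
                  + df.n_hs * (spec["HS"] - spec["LS"]))
        np.testing.assert_allclose(on.intensity - off.intensity, expect,
                                   atol=1e-12)

    def test_same_seed_is_bit_identical(self, xanes_truth):
        a = synth_timeseries("kalpha", xanes_truth, delays=[0.2, 1.0],
                             noise_level=0.05, seed=7)
        b = synth_timeseries("kalpha", xanes_truth, delays=[0.2, 1.0],
                             noise_level=0.05, seed=7)
        for (offa, ona), (offb, onb) in zip(a, b):
            np.testing.assert_array_equal(ona.intensity, onb.intensity)
            np.testing.assert_array_equal(offa.intensity, offb.intensity)

    def test_noise_matches_requested_sigma_at_peak(self, xanes_truth):
        # Monte-Carlo check of the counting-noise model at the peak channel
        level = 0.03
        peaks = []
        clean_off, _ = synth_timeseries("kalpha", xanes_truth, delays=[0.2],
                                        noise_level=0.0)[0]
        ipk = int(np.argmax(clean_off.intensity))
        for seed in range(500):
            off, _ = synth_timeseries("kalpha", xanes_truth, delays=[0.2],
                                      noise_level=level, seed=seed)[0]
            peaks.append(off.intensity[ipk])
        measured = np.std(peaks)
        expected = level * clean_off.intensity[ipk]
        assert abs(measured / expected - 1.0) < 0.10

    def test_negative_noise_rejected(self, xanes_truth):
        with pytest.raises(ValueError):
            synth_timeseries("kalpha", xanes_truth, noise_level=-0.1)


class TestKineticTrace:
    def test_pure_hs_weights_give_cascade_limited_trace(self, xanes_truth):
        tr = synth_kinetic_trace("xanes_amplitude", xanes_truth,
                                 weights=(0.0, 1.0), noise_level=0.0)
        i_pk = np.argmax(tr.signal)
        # HS observable peaks well after the IRF (population must feed in)
        assert tr.delay_ps[i_pk] > 3 * xanes_truth.irf_fwhm_ps

    def test_biexponential_construction(self, xanes_truth):
        from spincascade.kinetics import emg_response
        p = xanes_truth
        w = weights_for_biexp(0.7, 0.3, p)
        tr = synth_kinetic_trace("xanes_amplitude", p, weights=w,
                                 noise_level=0.0)
        expect = (0.7 * emg_response(tr.delay_ps, p.t0_ps, p.irf_fwhm_ps,
                                     p.tau1_ps)
                  + 0.3 * emg_response(tr.delay_ps, p.t0_ps, p.irf_fwhm_ps,
                                       p.tau3_ps))
        np.testing.assert_allclose(tr.signal, expect, atol=1e-12)

    def test_noiseless_refit_recovers_lifetimes(self, xanes_truth):
        from spincascade.kinetics import fit_trace
        p = xanes_truth
        tr = synth_kinetic_trace("xanes_amplitude", p,
                                 weights=weights_for_biexp(0.7, 0.3, p),
                                 noise_level=0.0)
        fit = fit_trace(tr, 2, n_boot=0)
        (a1, tau1), (a3, tau3) = fit.components
        assert abs(tau1 / p.tau1_ps - 1) < 1e-6
        assert abs(tau3 / p.tau3_ps - 1) < 1e-6
        assert abs(fit.irf_fwhm_ps / p.irf_fwhm_ps - 1) < 1e-6

    def test_longer_hs_lifetime_increases_trace_integral(self):
        integrals = []
        for tau3 in (4.0, 8.0, 16.0):
            p = CascadeParams(tau3_ps=tau3)
            tr = synth_kinetic_trace("xanes_amplitude", p, weights=(0.0, 1.0),
                                     delays=np.linspace(-1, 120, 600),
                                     noise_level=0.0)
            integrals.append(np.trapezoid(tr.signal, tr.delay_ps))
        assert integrals[0] < integrals[1] < integrals[2]

    def test_warns_when_rise_not_covered(self, xanes_truth):
        with pytest.warns(UserWarning, match="3\\*IRF"):
            synth_kinetic_trace("xanes_amplitude", xanes_truth,
                                delays=np.linspace(1.0, 50.0, 50),
                                noise_level=0.0)

    def test_fwhm_kind_uses_increment_weights(self, xanes_truth):
        tr = synth_kinetic_trace("kalpha_fwhm", xanes_truth, noise_level=0.0)
        df = simulate_populations(xanes_truth, tr.delay_ps)
        np.testing.assert_allclose(
            tr.signal, 0.7 * (df.n_is + df.n_hs), atol=1e-12)
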