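"""Synthetic Fe K-alpha / K-beta spectra and kinetic traces of a spin cascade.

The generator emulates the statistical structure of a femtosecond
pump-probe X-ray emission experiment on a ferric heme protein whose
photocycle is a sequential spin cascade LS (S=1/2) -> IS (S=3/2) ->
HS (S=5/2) -> LS:

* K-alpha doublet at 6404 / 6391 eV whose K-alpha-1 width grows linearly
  with the number of unpaired 3d electrons up to n = 3 and saturates
  beyond, with a high-spin minus low-spin FWHM excess of 0.7 eV;
* K-beta mainline (7058 eV) / K-beta' sideband (7043 eV) spin signature:
  amplitude transfers from mainline to sideband and the mainline
  blue-shifts as the spin rises;
* cascade populations under a Gaussian IRF (closed forms from
  :mod:`.kinetics`);
* counting-like heteroscedastic Gaussian noise, reproducible under a seed.

Species line widths are specified as target *numeric* FWHM values of the
asymmetric profile (the fitted observable), and every line is area-
normalized on the evaluation grid, so spin-state interconversion conserves
the total emission intensity exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .kinetics import CascadeParams, cascade_populations
from .lineshape import APVParams, apv_profile, numeric_fwhm
from .spectra_core import EnergySpectrum, KineticTrace

__all__ = [
    "SpinState", "SpeciesLineModel", "SPIN_STATES", "LS", "IS", "HS",
    "species_spectrum", "simulate_populations", "synth_timeseries",
    "synth_kinetic_trace", "weights_for_biexp",
    "default_xes_grid", "default_delays",
]


@dataclass(frozen=True)
class SpinState:
    """One of the three ferric spin states: LS, IS or HS."""

    name: str
    two_S: int       # twice the spin quantum number
    n_unpaired: int  # unpaired 3d electrons

    def __post_init__(self):
        allowed = {"LS": 1, "IS": 3, "HS": 5}
        if self.name not in allowed:
            raise ValueError("name must be one of LS, IS, HS")
        if self.two_S != allowed[self.name] or self.n_unpaired != self.two_S:
            raise ValueError(f"{self.name} requires two_S = n_unpaired = "
                             f"{allowed[self.name]}")


LS = SpinState("LS", 1, 1)
IS = SpinState("IS", 3, 3)
HS = SpinState("HS", 5, 5)
SPIN_STATES = {"LS": LS, "IS": IS, "HS": HS}


@dataclass(frozen=True)
class SpeciesLineModel:
    """Per-spin-state emission line parameters for both XES channels.

    K-alpha: two lines (K-alpha-1 at 6404 eV, K-alpha-2 at 6391 eV, area
    ratio 2:1 hence peak-amplitude ratio ~1:2) sharing a Lorentzian mixing
    ``kalpha_eta`` and a blue-flank asymmetry ``kalpha_asym``. The
    K-alpha-1 numeric FWHM excess over the low-spin value follows
    ``hs_broadening * min((n-1)/2, 1)`` — linear in the unpaired-electron
    count up to n = 3, saturated beyond, reaching ``hs_broadening``
    (default 0.7 eV) for the high-spin state. The excited-state doublet
    also gains blue-flank asymmetry (the broadening is more pronounced on
    the high-energy wing), which places the transient's positive lobe near
    6406 eV while the area-conserved loss at the line core keeps the
    negative lobe at 6404 eV.

    K-beta: mainline at 7058 eV plus K-beta' sideband at 7043 eV. Per spin
    step ((n-1)/2), an area fraction ``kbeta_transfer`` moves from the
    mainline to the sideband and the mainline shifts ``kbeta_main_shift``
    to the blue. Only the sign pattern of these changes is anchored to
    observed high-spin signatures; the magnitudes are free parameters.
    """

    # K-alpha channel
    kalpha1_center: float = 6404.0
    kalpha2_center: float = 6391.0
    kalpha_fwhm_ls: float = 2.8       # numeric FWHM of the LS K-alpha-1 (eV)
    kalpha_eta: float = 0.5
    kalpha_asym: float = -0.2         # 1/eV, slight red-tail asymmetry of the LS doublet
    kalpha_asym_is: float = 0.1       # extra blue-flank asymmetry of the IS doublet
    kalpha_asym_hs: float = 0.2       # extra blue-flank asymmetry of the HS doublet
    kalpha_shift_excited: float = 0.0  # eV rigid shift of the excited doublets
    kalpha1_area: float = 1.0         # arbitrary units * eV
    kalpha_area_ratio: float = 0.5    # K-alpha-2 : K-alpha-1 area
    hs_broadening: float = 0.7        # HS minus LS K-alpha-1 FWHM (eV)
    # K-beta channel
    kbeta_main_center: float = 7058.0
    kbeta_side_center: float = 7043.0
    kbeta_main_fwhm: float = 3.4
    kbeta_side_fwhm: float = 5.0
    kbeta_eta: float = 0.5
    kbeta_main_area: float = 1.0
    kbeta_side_area_ls: float = 0.10  # sideband area already present at LS
    kbeta_transfer: float = 0.08      # mainline->sideband area per spin step
    kbeta_main_shift: float = 0.3     # eV blue shift per spin step

    def spin_step(self, state: SpinState) -> float:
        return (state.n_unpaired - 1) / 2.0

    def kalpha1_fwhm_excess(self, state: SpinState) -> float:
        """Numeric K-alpha-1 FWHM excess over LS (eV): linear to n=3, then flat."""
        return self.hs_broadening * min(self.spin_step(state), 1.0)


DEFAULT_LINE_MODEL = SpeciesLineModel()


def default_xes_grid(channel: str, step_ev: float = 0.2) -> np.ndarray:
    """Default analysis grids: 6380-6420 eV (K-alpha), 7020-7080 eV (K-beta)."""
    if channel == "kalpha":
        lo, hi = 6380.0, 6420.0
    elif channel == "kbeta":
        lo, hi = 7020.0, 7080.0
    else:
        raise ValueError("channel must be 'kalpha' or 'kbeta'")
    n = int(round((hi - lo) / step_ev))
    return lo + step_ev * np.arange(n + 1)


def default_delays(start: float = -1.0, stop: float = 50.0,
                   n_linear: int = 41, n_log: int = 20) -> np.ndarray:
    """Delays with linear coverage of the rise and a log-spaced decay tail."""
    lin = np.linspace(start, 1.0, n_linear)
    log = np.geomspace(1.0, stop, n_log + 1)[1:]
    return np.concatenate([lin, log])


@lru_cache(maxsize=64)
def _fwhm0_for_numeric(target_fwhm: float, eta: float, asym: float) -> float:
    """Invert numeric_fwhm(fwhm0) = target at fixed (eta, asym)."""
    def f(w0):
        return numeric_fwhm(APVParams(1.0, 0.0, w0, eta, asym)) - target_fwhm
    lo, hi = 0.2 * target_fwhm, 3.0 * target_fwhm
    return brentq(f, lo, hi, xtol=1e-10)


def _area_normalized(grid: np.ndarray, p: APVParams, area: float) -> np.ndarray:
    """Evaluate one line scaled to the requested trapezoid area on ``grid``."""
    y = apv_profile(grid, p)
    raw = float(np.trapezoid(y, grid))
    if raw <= 0:
        raise ValueError("line has zero area on the supplied grid")
    return y * (area / raw)


def _kalpha_lines(state: SpinState, model: SpeciesLineModel):
    # the numeric FWHM saturates at n = 3 (the width does not evolve beyond
    # S = 3/2); excited states also gain blue-flank asymmetry (HS slightly
    # more than IS), which places the transient's positive lobe on the blue
    # wing and weights it toward the later-rising HS population
    target = model.kalpha_fwhm_ls + model.kalpha1_fwhm_excess(state)
    asym = model.kalpha_asym + {"LS": 0.0, "IS": model.kalpha_asym_is,
                                "HS": model.kalpha_asym_hs}[state.name]
    shift = 0.0 if state.name == "LS" else model.kalpha_shift_excited
    w0 = _fwhm0_for_numeric(target, model.kalpha_eta, asym)
    line1 = APVParams(1.0, model.kalpha1_center + shift, w0,
                      model.kalpha_eta, asym)
    line2 = APVParams(1.0, model.kalpha2_center + shift, w0,
                      model.kalpha_eta, asym)
    areas = (model.kalpha1_area, model.kalpha1_area * model.kalpha_area_ratio)
    return (line1, line2), areas


def _kbeta_lines(state: SpinState, model: SpeciesLineModel):
    step = model.spin_step(state)
    moved = model.kbeta_transfer * step * model.kbeta_main_area
    main_area = model.kbeta_main_area - moved
    side_area = model.kbeta_side_area_ls + moved
    main = APVParams(1.0, model.kbeta_main_center + model.kbeta_main_shift * step,
                     model.kbeta_main_fwhm, model.kbeta_eta, 0.0)
    side = APVParams(1.0, model.kbeta_side_center, model.kbeta_side_fwhm,
                     model.kbeta_eta, 0.0)
    return (main, side), (main_area, side_area)


def species_spectrum(channel: str, state: SpinState, grid=None,
                     model: SpeciesLineModel = DEFAULT_LINE_MODEL) -> EnergySpectrum:
    """Noiseless emission spectrum of one pure spin state.

    Each line is area-normalized on the evaluation grid, so the three spin
    states carry identical total emission intensity and any population
    redistribution integrates to zero.
    """
    if not isinstance(state, SpinState):
        state = SPIN_STATES[state]
    if grid is None:
        grid = default_xes_grid(channel)
    grid = np.asarray(grid, dtype=float)
    if channel == "kalpha":
        lines, areas = _kalpha_lines(state, model)
    elif channel == "kbeta":
        lines, areas = _kbeta_lines(state, model)
    else:
        raise ValueError("channel must be 'kalpha' or 'kbeta'")
    for p in lines:
        halfspan = 3.0 * p.fwhm0_ev
        if grid[0] > p.center_ev - halfspan or grid[-1] < p.center_ev + halfspan:
            raise ValueError(
                f"grid must cover {p.center_ev} +- 3*FWHM ({halfspan:.1f} eV)")
    intensity = np.zeros_like(grid)
    for p, area in zip(lines, areas):
        intensity = intensity + _area_normalized(grid, p, area)
    return EnergySpectrum(grid, intensity, channel=channel, laser_state="n/a")


def simulate_populations(params: CascadeParams, delays) -> pd.DataFrame:
    """Populations of the sequential cascade at each delay.

    Columns: ``delay_ps, n_is, n_hs, n_gs`` with ``n_gs = 1 - n_is - n_hs``
    (molecules are either still cascading or back in the ground state).
    """
    delays = np.asarray(delays, dtype=float)
    n_is, n_hs = cascade_populations(delays, params)
    return pd.DataFrame({
        "delay_ps": delays,
        "n_is": n_is,
        "n_hs": n_hs,
        "n_gs": 1.0 - n_is - n_hs,
    })


def _counting_noise_sigma(clean: np.ndarray, noise_level: float) -> np.ndarray:
    """sigma(E) = noise_level * max * sqrt(I(E)/max): Poisson-like scaling."""
    peak = float(np.max(clean))
    return noise_level * peak * np.sqrt(np.clip(clean, 0.0, None) / peak)


def synth_timeseries(channel: str, params: CascadeParams, delays=None,
                     noise_level: float = 0.02, seed: int = 0,
                     model: SpeciesLineModel = DEFAULT_LINE_MODEL,
                     grid=None) -> list[tuple[EnergySpectrum, EnergySpectrum]]:
    """(laser-off, laser-on) spectrum pairs across the delay scan.

    laser_on(E, t) = (1 - N_IS - N_HS) * LS + N_IS * IS + N_HS * HS plus
    heteroscedastic counting noise; the laser-off frame is the pure
    low-spin spectrum with an independent noise draw. ``noise_level`` is
    the relative 1-sigma at the spectrum peak; 0 gives noiseless pairs.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    if delays is None:
        delays = default_delays()
    delays = np.asarray(delays, dtype=float)
    if grid is None:
        grid = default_xes_grid(channel)
    rng = np.random.default_rng(seed)
    spec = {name: species_spectrum(channel, st, grid, model)
            for name, st in SPIN_STATES.items()}
    n_is, n_hs = cascade_populations(delays, params)
    pairs = []
    for j, t in enumerate(delays):
        on_clean = ((1.0 - n_is[j] - n_hs[j]) * spec["LS"].intensity
                    + n_is[j] * spec["IS"].intensity
                    + n_hs[j] * spec["HS"].intensity)
        off_clean = spec["LS"].intensity
        if noise_level > 0:
            s_on = _counting_noise_sigma(on_clean, noise_level)
            s_off = _counting_noise_sigma(off_clean, noise_level)
            on = on_clean + rng.normal(0.0, 1.0, on_clean.size) * s_on
            off = off_clean + rng.normal(0.0, 1.0, off_clean.size) * s_off
        else:
            s_on = s_off = None
            on, off = on_clean, off_clean
        pairs.append((
            EnergySpectrum(grid, off, sigma=s_off, channel=channel,
                           laser_state="off", delay_ps=float(t)),
            EnergySpectrum(grid, on, sigma=s_on, channel=channel,
                           laser_state="on", delay_ps=float(t)),
        ))
    return pairs


def weights_for_biexp(a1: float, a3: float, params: CascadeParams
                      ) -> tuple[float, float]:
    """Per-state observable weights (w_IS, w_HS) that make the cascade trace
    an IRF-convolved biexponential with amplitudes exactly (a1, a3).

    Inverts  w_IS*N_IS + w_HS*N_HS = a1*H(tau1) + a3*H(tau3).
    """
    tau1, tau3, f = params.tau1_ps, params.tau3_ps, params.f_exc
    if abs(tau3 - tau1) < 1e-6 * tau1:
        raise ValueError("amplitude mapping is singular for tau1 == tau3")
    w_hs = a3 * (tau3 - tau1) / (f * tau3)
    w_is = (a1 + a3) / f
    return w_is, w_hs


def synth_kinetic_trace(kind: str, params: CascadeParams,
                        weights: tuple[float, float] | None = None,
                        delays=None, noise_level: float = 0.05,
                        seed: int = 0,
                        model: SpeciesLineModel = DEFAULT_LINE_MODEL
                        ) -> KineticTrace:
    """Scalar kinetic trace w_IS*N_IS(t) + w_HS*N_HS(t) plus Gaussian noise.

    ``kind='xanes_amplitude'`` is the edge-energy absorption transient
    (default weights equal for IS and HS: their doming signals are not
    distinguished); ``kind='kalpha_fwhm'`` uses the per-state K-alpha-1
    FWHM excess as weights, so the trace is the model line broadening in
    eV over the low-spin value. Noise is homoscedastic with
    ``sigma = noise_level * max |signal|``.
    """
    if kind not in ("xanes_amplitude", "kalpha_fwhm"):
        raise ValueError("kind must be 'xanes_amplitude' or 'kalpha_fwhm'")
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    if delays is None:
        delays = default_delays()
    delays = np.asarray(delays, dtype=float)
    lo_needed = params.t0_ps - 3.0 * params.irf_fwhm_ps
    hi_needed = params.t0_ps + 3.0 * params.irf_fwhm_ps
    if delays[0] > lo_needed or delays[-1] < hi_needed:
        warnings.warn("delay grid does not cover t0 +- 3*IRF; the rise "
                      "will be poorly constrained in fits", stacklevel=2)
    if weights is None:
        if kind == "xanes_amplitude":
            weights = (1.0, 1.0)
        else:
            weights = (model.kalpha1_fwhm_excess(IS),
                       model.kalpha1_fwhm_excess(HS))
    w_is, w_hs = weights
    n_is, n_hs = cascade_populations(delays, params)
    clean = w_is * n_is + w_hs * n_hs
    label = {"xanes_amplitude": "XANES@7125.3eV",
             "kalpha_fwhm": "Kalpha1 FWHM"}[kind]
    if noise_level == 0:
        return KineticTrace(delays, clean, label=label)
    rng = np.random.default_rng(seed)
    sig = noise_level * float(np.max(np.abs(clean)))
    noisy = clean + rng.normal(0.0, sig, clean.size)
    return KineticTrace(delays, noisy, sigma=np.full(clean.size, sig),
                        label=label)
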