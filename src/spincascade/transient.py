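"""Build, normalize, shift-match and window-integrate difference spectra.

A transient is the laser-on minus laser-off spectrum at one pump-probe
delay. Sign convention throughout: a positive ``shift`` in `best_shift`
moves the reference ``b`` to *higher* energy before comparison, i.e. the
returned shift is the energy displacement that must be applied to ``b``
to overlay ``a``.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np

from .spectra_core import EnergySpectrum, KineticTrace, TransientSpectrum, resample

__all__ = ["make_transient", "normalize_to_max", "best_shift",
           "integrate_window", "ShiftMatch"]


def make_transient(on: EnergySpectrum, off: EnergySpectrum) -> TransientSpectrum:
    """On-minus-off difference on the overlap of the two grids.

    The laser-off spectrum is linearly resampled onto the laser-on grid
    restricted to the overlapping energy range; uncertainties are
    propagated in quadrature when both spectra carry them.
    """
    if on.channel != off.channel:
        raise ValueError(f"channel mismatch: {on.channel} vs {off.channel}")
    lo = max(on.energy_ev[0], off.energy_ev[0])
    hi = min(on.energy_ev[-1], off.energy_ev[-1])
    if lo >= hi:
        raise ValueError("spectra have disjoint energy ranges")
    mask = (on.energy_ev >= lo) & (on.energy_ev <= hi)
    grid = on.energy_ev[mask]
    off_r = resample(off, grid)
    delta = on.intensity[mask] - off_r.intensity
    if on.sigma is not None and off_r.sigma is not None:
        sigma = np.hypot(on.sigma[mask], off_r.sigma)
    else:
        sigma = None
    return TransientSpectrum(grid, delta, sigma=sigma, delay_ps=on.delay_ps,
                             channel=on.channel)


def normalize_to_max(t: TransientSpectrum) -> TransientSpectrum:
    """Scale so that max |delta| = 1 (idempotent, scale-invariant)."""
    peak = float(np.max(np.abs(t.delta)))
    if peak == 0:
        raise ValueError("cannot normalize an identically zero transient")
    sigma = None if t.sigma is None else t.sigma / peak
    return TransientSpectrum(t.energy_ev, t.delta / peak, sigma=sigma,
                             delay_ps=t.delay_ps, channel=t.channel,
                             normalized=True)


class ShiftMatch(NamedTuple):
    shift_ev: float
    scale: float
    rms: float


def _shift_rms(a: TransientSpectrum, b: TransientSpectrum, shift: float,
               allow_scale: bool, min_overlap: float):
    """RMS of a(E) - scale*b(E - shift) over the overlap; None if too small."""
    lo = max(a.energy_ev[0], b.energy_ev[0] + shift)
    hi = min(a.energy_ev[-1], b.energy_ev[-1] + shift)
    span_a = a.energy_ev[-1] - a.energy_ev[0]
    if hi - lo < min_overlap * span_a:
        return None
    mask = (a.energy_ev >= lo) & (a.energy_ev <= hi)
    if mask.sum() < 3:
        return None
    e = a.energy_ev[mask]
    av = a.delta[mask]
    bv = np.interp(e - shift, b.energy_ev, b.delta)
    if allow_scale:
        denom = float(bv @ bv)
        scale = float(av @ bv) / denom if denom > 0 else 0.0
    else:
        scale = 1.0
    r = av - scale * bv
    return float(np.sqrt(np.mean(r * r))), scale


def best_shift(a: TransientSpectrum, b: TransientSpectrum,
               shift_range: tuple[float, float] = (-3.0, 3.0),
               allow_scale: bool = False,
               step: float = 0.05,
               min_overlap: float = 0.5) -> ShiftMatch:
    """Energy shift (and optional scale) that best overlays ``b`` on ``a``.

    Grid search at ``step`` eV resolution over ``shift_range`` followed by
    parabolic refinement of the minimum; the scale, when allowed, is the
    closed-form least-squares solution at each shift. Shifts that leave
    less than ``min_overlap`` of a's window overlapping are skipped.
    """
    lo, hi = shift_range
    shifts = lo + step * np.arange(int(round((hi - lo) / step)) + 1)
    rms = np.full(shifts.size, np.inf)
    for i, s in enumerate(shifts):
        out = _shift_rms(a, b, s, allow_scale, min_overlap)
        if out is not None:
            rms[i] = out[0]
    if not np.any(np.isfinite(rms)):
        raise ValueError("no shift in range leaves sufficient overlap")
    i0 = int(np.argmin(rms))
    best = shifts[i0]
    # parabolic refinement through the three bracketing points
    if 0 < i0 < shifts.size - 1 and np.isfinite(rms[i0 - 1]) \
            and np.isfinite(rms[i0 + 1]) and rms[i0] > 0:
        y0, y1, y2 = rms[i0 - 1], rms[i0], rms[i0 + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            offset = 0.5 * (y0 - y2) / denom
            if abs(offset) <= 1.0:
                best = shifts[i0] + offset * step
    out = _shift_rms(a, b, best, allow_scale, min_overlap)
    if out is None or out[0] > rms[i0]:
        best = shifts[i0]
        out = _shift_rms(a, b, best, allow_scale, min_overlap)
    return ShiftMatch(float(best), float(out[1]), float(out[0]))


def integrate_window(series: Sequence[TransientSpectrum],
                     window: tuple[float, float]) -> KineticTrace:
    """Trapezoidal integral of each transient over ``window`` versus delay.

    Every transient must carry a delay and cover the window; the integral
    uncertainty combines point sigmas in quadrature with their trapezoid
    weights. Disjoint windows that share a grid-point boundary add exactly.
    """
    lo, hi = window
    delays, values, sigmas = [], [], []
    have_sigma = True
    for t in series:
        if t.delay_ps is None:
            raise ValueError("every transient needs a delay_ps for a trace")
        e = t.energy_ev
        if lo < e[0] or hi > e[-1]:
            raise ValueError(f"window [{lo}, {hi}] outside grid "
                             f"[{e[0]}, {e[-1]}]")
        mask = (e >= lo) & (e <= hi)
        ew, dw = e[mask], t.delta[mask]
        values.append(float(np.trapezoid(dw, ew)))
        delays.append(t.delay_ps)
        if t.sigma is None:
            have_sigma = False
        else:
            # trapezoid weights: (e[i+1]-e[i-1])/2, half-steps at the edges
            w = np.zeros(ew.size)
            w[1:] += 0.5 * np.diff(ew)
            w[:-1] += 0.5 * np.diff(ew)
            sigmas.append(float(np.sqrt(np.sum((t.sigma[mask] * w) ** 2))))
    order = np.argsort(delays)
    delays = np.asarray(delays)[order]
    values = np.asarray(values)[order]
    sig = np.asarray(sigmas)[order] if have_sigma and sigmas else None
    return KineticTrace(delays, values, sigma=sig,
                        label=f"integral[{lo:g},{hi:g}]eV")
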