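"""Photoexcitation-yield accounting.

Two independent estimates of the excited molecular fraction are compared:

* ``excited_fraction`` — forward estimate from the experimental
  parameters: pump fluence, wavelength, chromophore concentration, jet
  thickness and molar absorptivity, through decadic Beer-Lambert
  absorption averaged over the sample depth,

      A = eps * c * l,
      f = Phi * (1 - 10^(-A)) / N_area,

  with ``Phi`` the photon areal density and ``N_area`` the molecules per
  unit area. The closed form is the depth integral of the local absorbed
  photon density, not a front-surface approximation (at millimolar
  concentration and Soret-band absorptivity A is of order one, where the
  difference matters).

* ``observed_fraction`` — the least-squares scale of a full-conversion
  reference transient onto a measured transient.

Agreement within a factor of 2 (``consistency_ratio``) is the coarse
check that essentially all photoexcited molecules follow the observed
relaxation pathway. Pump scattering and reflection losses are not
modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.constants import Avogadro, c as _c_light, h as _h_planck

from .spectra_core import TransientSpectrum

__all__ = ["ExcitationConditions", "excited_fraction", "observed_fraction",
           "consistency_ratio", "ObservedYield", "RatioReport"]


@dataclass(frozen=True)
class ExcitationConditions:
    """Pump and sample parameters of one excitation-yield estimate."""

    fluence_mj_cm2: float   # pump fluence (mJ/cm^2)
    wavelength_nm: float    # pump wavelength (nm)
    conc_mM: float          # chromophore concentration (mmol/L)
    path_um: float          # jet / sample thickness (um)
    eps_M_cm: float         # decadic molar absorptivity (M^-1 cm^-1)

    def __post_init__(self):
        for name in ("fluence_mj_cm2", "wavelength_nm", "conc_mM",
                     "path_um", "eps_M_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def absorbance(self) -> float:
        """Decadic absorbance A = eps * c * l."""
        return (self.eps_M_cm * self.conc_mM * 1e-3 * self.path_um * 1e-4)


def excited_fraction(cond: ExcitationConditions) -> float:
    """Depth-averaged excited fraction from Beer-Lambert absorption.

    Capped at 1 (with a saturation warning): more absorbed photons than
    molecules means every molecule in the column is excited at least once.
    """
    e_photon = _h_planck * _c_light / (cond.wavelength_nm * 1e-9)  # J
    phi = cond.fluence_mj_cm2 * 1e-3 / e_photon        # photons / cm^2
    absorbed = phi * (1.0 - 10.0 ** (-cond.absorbance))
    n_area = (cond.conc_mM * 1e-3 * 1e-3) * (cond.path_um * 1e-4) * Avogadro
    frac = absorbed / n_area
    if frac > 1.0:
        warnings.warn(f"excitation saturated: nominal fraction {frac:.3g} "
                      "capped at 1", stacklevel=2)
        return 1.0
    return float(frac)


class ObservedYield(NamedTuple):
    fraction: float
    relative_residual: float
    mismatch: bool


#: shape disagreement above which the scale estimate is flagged unreliable
MISMATCH_RESIDUAL = 0.5


def observed_fraction(transient: TransientSpectrum,
                      full_conversion_reference: TransientSpectrum
                      ) -> ObservedYield:
    """Excited fraction as the least-squares scale of the 100%-conversion
    reference difference onto the measured transient.

    The returned ``relative_residual`` is the post-scaling residual RMS
    over the transient RMS; when it exceeds 0.5 the shapes disagree and
    the scale is flagged as a mismatch rather than a yield.
    """
    lo = max(transient.energy_ev[0], full_conversion_reference.energy_ev[0])
    hi = min(transient.energy_ev[-1], full_conversion_reference.energy_ev[-1])
    if lo >= hi:
        raise ValueError("transient and reference grids are disjoint")
    mask = (transient.energy_ev >= lo) & (transient.energy_ev <= hi)
    e = transient.energy_ev[mask]
    t = transient.delta[mask]
    r = np.interp(e, full_conversion_reference.energy_ev,
                  full_conversion_reference.delta)
    denom = float(r @ r)
    if denom == 0:
        raise ValueError("full-conversion reference is identically zero")
    scale = float(t @ r) / denom
    resid = t - scale * r
    t_rms = float(np.sqrt(np.mean(t * t)))
    rel = float(np.sqrt(np.mean(resid * resid))) / t_rms if t_rms > 0 else 1.0
    return ObservedYield(scale, rel, rel > MISMATCH_RESIDUAL)


class RatioReport(NamedTuple):
    ratio: float
    agree_within_factor_2: bool
    f_expected: float
    f_observed: float


def consistency_ratio(f_expected: float, f_observed: float) -> RatioReport:
    """max/min ratio of the two yield estimates; agreement flag at ratio <= 2."""
    for name, f in (("f_expected", f_expected), ("f_observed", f_observed)):
        if not 0.0 < f <= 1.0:
            raise ValueError(f"{name} must lie in (0, 1], got {f}")
    ratio = max(f_expected, f_observed) / min(f_expected, f_observed)
    return RatioReport(float(ratio), ratio <= 2.0,
                       float(f_expected), float(f_observed))
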