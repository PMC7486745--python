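# spincascade

Analysis tools for femtosecond pump-probe X-ray spectroscopy of
spin-crossover metalloproteins — the reduction chain by which a
photoinduced spin cascade in a ferric heme (low-spin S=1/2 → intermediate
S=3/2 → high-spin S=5/2 → ground state) is established from Fe Kα / Kβ
X-ray emission and Fe K-edge absorption data.

It is written for experimentalists reducing beamline data (plain-text
spectra and kinetic traces) and for anyone who wants to study how reliably
such a cascade can be extracted at realistic noise levels: a first-class
synthetic-data generator reproduces the statistical structure of the
experiment, so every stage of the pipeline is testable without access to
facility data.

## What it computes

**Line-shape fitting.** Emission lines are modelled as asymmetric
pseudo-Voigt profiles

    I(E) = A·[η·L(E) + (1−η)·G(E)],   Γ(E) = 2·w₀ / (1 + exp(−a·(E−E₀))),

where L and G are unit-height Lorentzian/Gaussian of FWHM Γ(E) and the
sigmoidal width makes one flank broader than the other. The Kα₁ (6404 eV)
and Kα₂ (6391 eV) lines are fitted jointly with a shared baseline; the
observable is the numerically extracted FWHM of Kα₁, which grows with the
number of unpaired 3d electrons (saturating above S = 3/2, with a
high-spin − low-spin excess of 0.7 eV).

**Transient spectra.** Laser-on minus laser-off differences, normalization,
rigid shift-and-scale matching against reference difference spectra (the
Kβ mainline/Kβ′ sideband spin fingerprint), and window integration into
kinetic traces.

**Kinetics.** Observables follow an IRF-convolved multi-exponential,
built from the exact Gaussian ⊗ exponential response

    H(t) = ½·exp(σ²/2τ² − (t−t₀)/τ)·erfc((σ/τ − (t−t₀)/σ)/√2),

with the sequential cascade GS → IS --(τ₁)--> HS --(τ₃)--> GS in closed
form. Fits report 68% confidence intervals from a seeded
residual-resampling bootstrap, and a bi- vs tri-exponential comparison
(AICc + per-component weakness flags) guards against over-fitting.

**Yield accounting.** The expected excitation fraction from pump fluence,
wavelength, concentration, path length and molar absorptivity
(depth-averaged decadic Beer-Lambert), compared against the fraction
observed from transient amplitudes — consistent pathways agree within a
factor of 2.

## Worked example

Fit one noisy synthetic kinetic trace generated from the cascade model:

```python
import spincascade as sc

truth = sc.CascadeParams(t0_ps=0.0, irf_fwhm_ps=0.14, tau1_ps=0.61,
                         tau3_ps=8.7, f_exc=0.3)
trace = sc.synth_kinetic_trace(
    "xanes_amplitude", truth,
    weights=sc.weights_for_biexp(0.70, 0.30, truth),
    noise_level=0.05, seed=1)
fit = sc.fit_trace(trace, n_components=2, n_boot=200, seed=0)
print(f"IRF-limited rise (tau_r): {fit.irf_fwhm_ps:.3f} ps")
for i, (a, tau) in enumerate(fit.components, start=1):
    lo, hi = fit.ci68[f"tau{i}"]
    print(f"component {i}: a = {a:+.3f}, tau = {tau:.2f} ps "
          f"(68% CI {lo:.2f}-{hi:.2f})")
```

prints

```
IRF-limited rise (tau_r): 0.125 ps
component 1: a = +0.696, tau = 0.65 ps (68% CI 0.56-0.73)
component 2: a = +0.279, tau = 9.61 ps (68% CI 7.57-12.24)
```

The generating truth (rise 0.14 ps, fast decay 0.61 ps with 70% weight,
slow decay 8.7 ps) is recovered within the bootstrap intervals: the fast
component is the intermediate-spin state feeding the high-spin state, the
slow one the high-spin state returning to the ground state.

The same analysis, end to end (simulation, doublet fits, transients, spin
classification, yield check, manifest with content hashes):

```sh
spincascade run-all --out-dir results/demo
```

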