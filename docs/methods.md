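# Methods

This note records the models, numerical choices and deliberate design
decisions behind `spincascade`, and what the synthetic-data experiments
do and do not demonstrate about real measurements.

## The physical picture

A ferric heme protein is photoexcited into the porphyrin π–π* bands. The
excitation relaxes through metal-centred spin states: an intermediate-spin
S = 3/2 state is populated essentially within the instrument response,
decays with a sub-picosecond constant τ₁ into the high-spin S = 5/2 state,
which returns to the S = 1/2 ground state with a constant τ₃ of several
picoseconds. Three X-ray observables track this cascade:

* the Fe Kα₁ emission line broadens with the number of unpaired 3d
  electrons (2p–3d exchange), linearly up to S = 3/2 and saturating
  beyond;
* the Fe Kβ mainline (7058 eV) loses intensity and blue-shifts while the
  Kβ′ sideband (7043 eV) grows — the classic 3p–3d spin marker;
* the Fe K-edge absorption at the edge energy grows when the Fe–N bonds
  elongate (doming), i.e. with the summed IS + HS population.

## Emission line model

One line is an asymmetric pseudo-Voigt: a linear Lorentzian/Gaussian blend
of common FWHM Γ(E) that varies sigmoidally across the line,
Γ(E) = 2·fwhm0/(1 + exp(−asym·(E−E₀))). This construction keeps the
maximum exactly at E₀ with height A for any asymmetry (the width function
only warps the abscissa), reduces exactly to the symmetric pseudo-Voigt at
asym = 0, and has one free asymmetry parameter. Because Γ varies, the
profile's true FWHM differs from fwhm0; it is always extracted numerically
(bisection on each flank of the maximum, 1e-6 eV tolerance, checked
against a brute-force dense-grid scan). Voigt-by-convolution profiles and
physical multiplet structure are out of scope.

The Kα doublet is fitted jointly — eleven parameters: five per line plus a
constant baseline — by bounded nonlinear least squares (lmfit), weights
1/σ² when uncertainties are present. Laser-on spectra are by default
seeded from the laser-off fit with only amplitudes, widths and baseline
free; centers, mixing and asymmetry are inherited. This stabilizes fits of
weak excited-state signals; a fully free mode is available. Which
parameters the original analyses shared between on and off fits is not
public, so this default is a declared choice of this package.

## Synthetic species library

The generator is the package's stand-in for beamline data, which are not
publicly deposited. Its defaults define the study conditions and were
fixed once, at design time:

* Kα₁ = 6404 eV, Kα₂ = 6391 eV, area ratio 2:1 (hence peak ratio ≈ 1:2),
  low-spin Kα₁ FWHM 2.8 eV (a typical Fe Kα width; the true instrumental
  width is a free parameter), η = 0.5.
* FWHM-vs-spin law: numeric-FWHM excess 0.7·min((n−1)/2, 1) eV for n
  unpaired electrons. Widths are specified as *target numeric FWHM* and
  the internal fwhm0 is root-solved, so the law is exact in the fitted
  observable and the laser-on/off round trip recovers 0.7 eV by
  construction rather than approximately.
* Asymmetry: the low-spin doublet carries a slight red-tail asymmetry
  (asym = −0.2 /eV); excited states gain blue-flank asymmetry (+0.1 IS,
  +0.2 HS), with no center shift. This realizes, within the
  area-conserving model, the observed transient structure: the deficit
  of the broadened line sits at the Kα₁ core (negative lobe at 6404 eV),
  the gain on the blue wing (positive lobe at 6406 eV), the broadening is
  more pronounced blue of the line, and — because the high-spin state is
  slightly more blue-asymmetric than the intermediate one — the positive
  lobe is weighted toward the later-rising HS population and rises more
  slowly than the negative lobe. The HS/IS magnitudes here are free
  parameters of the generator, not published values; only the sign
  pattern is anchored.
* Every line is area-normalized on the evaluation grid, so spin
  interconversion conserves total emission intensity exactly and the
  full-window transient integral vanishes identically on any grid.
* Kβ: mainline area transfers to the sideband (8% per spin step) and the
  mainline shifts +0.3 eV per step; magnitudes again free, signs anchored.
* XANES is represented only as a scalar amplitude at the edge energy
  (7125.3 eV) proportional to a weighted IS+HS population — no edge
  simulation. The IS and HS doming weights are not distinguishable in
  the source observable, so they default to equal.
* Noise: spectra get heteroscedastic Gaussian noise with
  σ(E) = level·max·sqrt(I(E)/max) (counting statistics); traces get
  homoscedastic noise at a fraction of the peak. All draws are seeded.
* Default grids 6380–6420 / 7020–7080 eV at 0.2 eV; delays −1 → 50 ps,
  linear through the rise then log-spaced. Excited fraction default 0.3,
  of the order implied by the fluence accounting below.

What passing these tests shows: the estimators are unbiased and correctly
calibrated *for data whose generating process matches the model* (exact
line shapes, exact kinetic model, Gaussian noise). What they do not show:
robustness to backgrounds, detector nonlinearity, jitter, or model
mismatch in the line shape — real data carry all of these.

## Kinetics

The elementary response is the exponentially modified Gaussian — the
exact convolution of a unit-area Gaussian IRF with a causal exponential —
evaluated via `erfcx` with a plain-exponential branch far past the rise,
finite for σ/τ from 0 to very large values (verified against adaptive
quadrature at 1e-8 across σ/τ ∈ [0.01, 10]). The rise constant reported
by fits is the Gaussian IRF FWHM; alternative conventions (10–90% rise)
are not used.

The sequential cascade has closed-form populations
N_IS = f·H(τ₁), N_HS = f·τ₃/(τ₃−τ₁)·[H(τ₃)−H(τ₁)], with an analytic
derivative-based branch when |τ₃−τ₁| < 1e-6·τ₁ (verified against
Runge–Kutta integration of the rate equations at 1e-6). Observed traces
are fitted with the *biexponential* observable model rather than the
cascade itself, matching how such data are reported; the cascade maps the
fast amplitude to the IS branch and the slow one to the HS branch, and
`weights_for_biexp` inverts that mapping so ensembles can be generated
with prescribed biexponential amplitudes.

Fitting uses unbounded Levenberg–Marquardt with lifetimes and the IRF
width in log space (positivity built in, log-arguments clipped to ±20 to
keep exploratory steps finite). Initialization is heuristic (half-rise
t₀, geometric-ladder lifetimes); a three-component fit is seeded from the
two-component solution plus a small component at the geometric-mean
lifetime, so the extra component measures what the data demand beyond two
exponentials instead of collapsing onto a cancelling degenerate pair.
Residual weighting is 1/σ² when uncertainties exist, uniform otherwise.

Confidence intervals are 68% percentile intervals from seeded
residual-resampling bootstrap (default 200 replicates) rather than
covariance linearization — the lifetimes are strongly nonlinear
parameters. The bootstrap is itself calibrated: over 300 simulated traces
at 5% noise the τ₁ interval covers the truth at a rate within [60%, 76%].

`compare_models` reports residual RMS, the small-sample-corrected Akaike
criterion and per-component amplitude intervals. A component is flagged
weak when its amplitude interval spans zero, its uncertainty is at least
as large as the amplitude, or it carries under 10% of the total weight;
components beyond the AICc-preferred model count are additionally marked
unsupported. The union of these flags is the package's operational
reading of "weak weight, large uncertainty": a 68% interval alone covers
a truly-zero amplitude only ~68% of the time and cannot by itself serve
as a reliable spurious-component detector.

## Transients, fingerprinting, yield

Differences are formed on the overlap of the two grids with the
laser-off spectrum linearly resampled onto the laser-on grid; no
smoothing or filtering anywhere (it would bias the FWHM observable).
Shift matching is a 0.05 eV grid search with parabolic refinement;
positive shift moves the reference to higher energy. Spin classification
ranks normalized references by post-shift-and-scale residual RMS and
raises an ambiguity caveat when the top two differ by under 10% — a Kβ
transient alone often cannot separate S = 3/2 from S = 5/2. The packaged
reference library is synthetic (generated from the species models);
users supply their own measured references for real assignments.

The expected excitation fraction uses depth-averaged decadic
Beer–Lambert absorption, f = Φ(1−10^(−A))/N_area — not a front-surface
approximation, because at millimolar concentration and Soret-band
absorptivity A is of order 1. Pump scattering and reflection losses are
not modelled. The default absorptivity (2×10⁴ M⁻¹cm⁻¹ at 400 nm) and jet
thickness (100 µm) are documented placeholders to be overridden with
measured values. The observed fraction is the least-squares scale of a
full-conversion reference transient; a relative residual above 0.5 flags
a shape mismatch instead of a yield. The two estimates are compared as a
max/min ratio with the agreement threshold at 2.

## Pipeline

One YAML-validated configuration drives simulate → line-shape fits →
transients → kinetics → classification → yield. Every run writes TSV
tables plus a manifest with SHA-256 hashes of all outputs; identical
configuration and seeds reproduce the hashes bit for bit. The
command-line interface is a thin layer over the library functions.

## Problem sizes

Validation experiments use 200-trace ensembles at 5% peak noise for
parameter recovery, 300 simulations × 100 bootstrap replicates for
interval calibration, 100 simulations for the model-comparison check,
and 500 draws for the noise-model check — sizes at which the ensemble
medians and rates are stable to well inside the tolerances tested.

## Known limitations

* The line model is empirical; it does not encode 3p–3d/2p–3d exchange
  physics, only its phenomenological consequences.
* The XANES channel is a single-energy amplitude; edge-shape changes and
  oxidation-state comparisons require externally supplied spectra.
* The Kβ spin-signature magnitudes and the excited-state asymmetry
  increments are free generator parameters, anchored only in sign.
* Population analysis assumes a strictly sequential cascade; parallel
  relaxation channels (e.g. a vibrationally hot ground state) are not
  modelled.
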