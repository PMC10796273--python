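# Methods

This note records the models implemented in qbetkit, the conventions and
defaults chosen where the methodology is genuinely open, and what the
synthetic generators do and do not emulate.

## Voltammetric kinetics

**Model.** A one-electron redox couple at a planar electrode with
Butler–Volmer kinetics. The analysis chain is the classical
peak-separation route to the standard heterogeneous rate constant k⁰:

* transfer coefficient from the peak-shift slope,
  `slope = −2.3·R·T/(α·n·F)` per decade of scan rate, regressed on
  (Ep − E_formal) vs log₁₀(v) with E_formal taken as the peak-pair midpoint;
* Nicholson's kinetic parameter from the closed-form working curve
  `ψ = 2.18·(α/π)^½·exp[−(α²F/RT)·n·ΔEp]` (ΔEp in volts);
* `k⁰ = ψ·(π·D·n·v·F/RT)^½` per scan rate, summarised as mean ± s.d.

**Constants and defaults.** F = 96485 C mol⁻¹, R = 8.314 J mol⁻¹ K⁻¹,
decade factor 2.3 exactly (so hand checks against the working formula
agree), T defaults to 298.15 K. The diffusion coefficient D has **no
default**: it is a required configuration value (~10⁻⁶ cm² s⁻¹ is a typical
literature magnitude for cytochrome c) and its absence is a configuration
error, never a silent fallback.

**Validity guard.** The closed-form ψ(ΔEp) expression is an
irreversible-region approximation. Peak pairs with ΔEp < 61/n mV are
excluded from k⁰ extraction with a near-reversibility warning; a study in
which every sweep is near-reversible is refused outright. Beyond the hard
guard, accurate recovery requires scan rates that place the couple well into
the quasi-irreversible regime: simulation shows the approximation
underestimates ψ by ~40–85% for ΔEp between 61 and ~110 mV, falling to a few
percent for ΔEp ≈ 135–250 mV. Round-trip validations therefore choose scan
rates so the predicted ψ lies in ~0.07–0.3 (via v = k⁰²/(c·ψ²) with
c = πDnF/RT), which is how a practitioner would design a scan-rate study
for this estimator.

**Transfer-coefficient convention.** For a Butler–Volmer couple the
irreversible cathodic peak shifts by −2.3RT/(2αnF) per decade, so the
slope formula above returns roughly **twice** the Butler–Volmer symmetry
factor of a simulated couple, drifting higher toward reversibility. The
fitted value (cathodic branch by default, anodic also computed) is always
reported, flagged when α > 1 and clipped at 1.5; but because of this
convention mismatch `analyze_study` accepts an explicit `alpha_ct` override,
and recovery validations use the known symmetry factor (0.5) there, matched
like D. Peak-separation ψ values for k⁰ are far more sensitive to α than
the regression is informative about it.

**Peak detection.** Each sweep branch gets a straight baseline fitted to
its leading 10%, box smoothing (window 5), and parabolic sub-sample
refinement of the extremum. A branch with no extremum above 3× the baseline
residual s.d. raises a no-peak error; equal-height ties break toward the
sweep midpoint with a warning. ΔEp > 1.5 V is rejected as a probable
mV-for-V unit error.

## Survival model and barrier fit

**Model.** Cell death at intrinsic rate r_d (proportional to donor
charging) gives `M(t) = e^(−r_d t)` for control-normalised metabolic
activity, hence `r_d = −ln M(t)/t` per well. The population update
`A → A·e^(−r_d·dt)` is exact, conserves A + D identically and composes as a
semigroup.

**Aggregation order.** r_d is computed per replicate well and then averaged
per (cell line, diameter, linker mass) condition — never from the mean
activity, which would bias the estimate under the log transform. Conditions
containing supranormal wells (M > 1, which control-normalised assays do
produce; the generator allows up to 1.5) keep their possibly negative rates
but are tagged, and a condition with mean r_d ≤ 0 is excluded from the
barrier fit with a warning.

**Barrier width.** The mass→length conversion for PEG defaults to the
contour length, 0.35 nm per 44.05 Da monomer (1 kDa ≈ 7.9 nm, 2 kDa ≈
15.9 nm); both factors are configurable because any effective-length
convention (helical, solvated) is equally defensible — the choice rescales
α_loc but not the exponential character of the decay.

**Fit.** `r_d(L) = β·e^(−α_loc·L)` by weighted nonlinear least squares
(weights 1/se² when every point has se > 0, otherwise unweighted),
initialised from — and reported alongside — the log-linear regression of
ln r_d on L; R² is computed on the untransformed scale. Parameter errors
are curvature-based and, when the weighted residuals exceed expectation,
inflated by √(reduced χ²) — never deflated. The inflation matters because
the per-condition standard errors are themselves estimates from few
replicates and the fit has few degrees of freedom; with plain curvature
errors the nominal 2-s.e. interval for α_loc covers the generating truth in
only ~85% of simulated datasets, with the conservative convention ~90%, in
line with its nominal level. A fitted α_loc ≤ 0 carries a "no barrier
decay" warning.

**Classical bound.** `d = k⁰/f`, converted cm → nm (×10⁷), reported at
full precision and rounded to one significant figure. The feasibility
verdict compares d to the linker length with an inclusive boundary
(d = L counts as classically possible).

## Spectral analysis

Difference spectra are formed after per-spectrum normalisation (default:
max; none/area selectable — the subtraction convention is not standardised,
and max-normalisation makes the result invariant to detector gain).
Operands are linearly interpolated onto their overlap at the finer native
step; subtraction is exactly antisymmetric under operand swap. Quantized
dips/peaks are local extrema above a prominence threshold
(scipy.signal.find_peaks), reported at the extremum grid point — grid steps
of ≤ 1 nm make sub-grid refinement unnecessary for these claims. Band
windows default to 380–450 nm (Soret), 500–580 nm (Q bands), 550–800 nm
(LSPR); the Soret redox call uses a 2 nm shift threshold (blueshift ≥
threshold ⇒ oxidized), all configurable since no numeric criterion is
standard.

## Synthetic generators

**Voltammograms.** One-electron quasi-reversible Butler–Volmer couple,
equal diffusion coefficients for both forms, semi-infinite planar
diffusion, explicit finite differences (stability ratio D·dt/dx² = 0.45,
slab of 6 diffusion lengths, 24 000 time steps by default — chosen so
halving both grid steps moves peak potentials by < 1 mV). Bulk contains
only the oxidized form at 1 mM over a 1 cm² electrode; current is reported
with the anodic branch positive; additive Gaussian current noise.
Deliberately not modelled: double-layer charging, uncompensated resistance,
convection/migration, and adsorbed-species (thin-layer) voltammetry — the
experimental couple is surface-tethered, but the analysis equations assume
diffusive voltammetry (D appears in the k⁰ expression), so the generator
follows the same diffusive treatment; a surface-confined simulator would be
the natural extension.

**Metabolic activity.** `M = exp(−β·e^(−α_loc·L)·t)·(1 + ε)`,
ε ~ N(0, σ), clipped to (0, 1.5]. Defaults are the resonance experiment's
design: diameters 20/50/100 nm, linkers 1/2/3.5/5 kDa, activity read at
12 h, nine replicates, σ = 0.05 (a realistic plate-reader CV for a
normalised viability assay). The generator has no genuine diameter effect,
no time-varying death rate, no plate/batch structure and no heavy-tailed
outliers — so passing recovery tests demonstrates estimator correctness
under the model's own assumptions, not robustness to real-assay artefacts.

**Spectra.** Baseline + signed Gaussian bands + additive Gaussian noise;
default band centres at 465/568/711 nm with the 612 nm bare-particle LSPR
and 536 nm dip available for round-trip tests. Photon (Poisson) noise and
Fano lineshapes are not modelled.

All generators draw every random number from one explicit integer seed per
call; identical parameters and seed give bit-identical output.

## Pipeline

Stages run in the order kinetics → qbet → spectral → feasibility, with the
kinetics k⁰ threaded into the feasibility stage when no explicit value is
configured. CSV dialect is fixed (comma, '.' decimal, mandatory header;
locale variants are rejected loudly). Reports are JSON with sorted keys;
with a fixed seed two runs differ only in the timestamp. Stage failures
exit with stage-specific codes (2 config, 3 kinetics, 4 qbet/feasibility,
5 spectral, 6 I/O) after flushing partial results with a `failed_at`
marker.

## Problem sizes used in validation

Kinetics round-trips use five scan rates per study at three true k⁰ values
on a 12 000-step grid; barrier-fit coverage uses 200 seeded datasets of
4 conditions × 9 replicates; spectral recovery uses 50 seeded difference
spectra. These sizes give stable pass/fail behaviour for the stochastic
properties while keeping the full suite fast.

## Known limitations

* The ψ(ΔEp) closed form is biased low near reversibility; the package
  guards and warns but cannot correct it — studies must be designed into
  the quasi-irreversible regime.
* The peak-shift transfer-coefficient regression and the Butler–Volmer
  symmetry factor differ by the factor-of-two slope convention described
  above; fitted α values should be read as diagnostics, not as the
  symmetry factor.
* Negative mean charging rates (activity gains) are excluded from the
  barrier fit rather than modelled.
* The spectral module detects and localises features; it does not model
  resonance-energy-transfer efficiency or fit lineshapes.
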