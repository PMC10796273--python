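# qbetkit

Analysis toolkit for **wirelessly driven redox chemistry at bio-functionalized
gold nanoparticles** — the experimental programme in which an alternating
electric field polarizes cytochrome-c/zinc-porphyrin-coated particles inside
cells, switches the haem redox state without wires, and the question is
whether the electron crosses the insulating PEG linker classically or by
quantum tunnelling.

The package implements the full quantitative chain of evidence:

1. **Voltammetric kinetics** (`qbetkit.kinetics`). From cyclic-voltammetry
   scan-rate studies it extracts the anodic/cathodic peak pair, the
   Butler–Volmer transfer coefficient α from the peak-shift slope
   `slope = −2.3RT/(αnF)`, Nicholson's kinetic parameter
   `ψ = 2.18·(α/π)^½ · exp[−(α²F/RT)·n·ΔEp]`, and the standard
   heterogeneous electron-transfer rate constant via
   `ψ = k⁰·[πDnvF/RT]^(−½)`.
2. **Survival → charging-rate → barrier fit** (`qbetkit.tunneling`). Cell
   metabolic activity normalised to untreated controls follows
   `M(t) = e^(−r_d·t)`; inverting gives the donor charging rate
   `r_d = −ln M(t)/t` per well. Fitting the per-condition mean rate against
   the PEG barrier width L with `r_d(L) = β·e^(−α_loc·L)` yields the inverse
   localization length α_loc — the exponential distance decay that is the
   signature of electron tunnelling.
3. **Classical-transport bound**. An electron transferring at rate k⁰ (cm/s)
   under a field of frequency f can classically cover at most `d = k⁰/f`
   per cycle; `qbetkit.tunneling.max_hop_distance` computes this in nm.
4. **Plasmon difference spectra** (`qbetkit.spectra`). Subtracting
   normalised scattering spectra of bare vs functionalized particles leaves
   quantized dips at molecular transitions; the module detects them, locates
   LSPR maxima in band windows, and calls haem redox switching from the
   Soret-band blueshift.
5. **Synthetic instruments** (`qbetkit.simulate`). Seeded generators for
   voltammograms (explicit finite-difference Butler–Volmer simulation),
   activity tables and spectra, so the whole chain is testable end to end
   without instrument data.

A `qbet` command-line tool (`qbetkit.cli`) orchestrates everything from a
single YAML/JSON config with reproducible JSON reports.

## Worked example

Simulate a metabolic-activity grid (100 nm particles, PEG linkers of
1/2/3.5/5 kDa, nine replicate wells, 5% noise, 12 h stimulation), extract
charging rates and fit the tunnelling barrier:

```python
from qbetkit import (MetabolicSimParams, simulate_metabolic_dataset,
                     aggregate_charging_rates, fit_barrier_decay,
                     max_hop_distance)

ds = simulate_metabolic_dataset(MetabolicSimParams(
    beta_true=0.1, alpha_loc_true=0.1, diameters=(100.0,),
    replicates=9, noise_sd_activity=0.05, seed=7))
rates = aggregate_charging_rates(ds)
for r in rates:
    print(f"L = {r.linker_length:5.1f} nm   r_d = {r.r_d:.4f} +/- {r.se:.4f} h^-1")
fit = fit_barrier_decay(rates)
print(f"alpha_loc = {fit.alpha_loc:.3f} +/- {fit.alpha_se:.3f} nm^-1")
print(f"beta      = {fit.beta:.3f} +/- {fit.beta_se:.3f} h^-1")
print(f"d_max     = {max_hop_distance(3.75e-3, 3.0e6):.4g} nm")
```

prints

```
L =   7.9 nm   r_d = 0.0459 +/- 0.0010 h^-1
L =  15.9 nm   r_d = 0.0213 +/- 0.0010 h^-1
L =  27.8 nm   r_d = 0.0105 +/- 0.0015 h^-1
L =  39.7 nm   r_d = 0.0038 +/- 0.0011 h^-1
alpha_loc = 0.088 +/- 0.008 nm^-1
beta      = 0.091 +/- 0.008 h^-1
d_max     = 0.0125 nm
```

The charging rate falls exponentially with barrier width (the fitted
α_loc covers the generating truth of 0.1 nm⁻¹ within two standard errors),
while the classical bound — a rate constant of 3.75 × 10⁻³ cm s⁻¹ driven at
3 MHz — limits a classical electron to ~0.01 nm per field cycle, three
orders of magnitude short of the 8–40 nm barrier. Classical transport
cannot explain the observed redox switching; exponential distance decay can.

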