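# dyespec

Tools for disentangling the blue shoulder of a cationic dye's visible
absorption band — methylene blue being the canonical case — into its two
physical contributions, and for propagating both into a model of plasmonic
nanocavity strong coupling.

The shoulder of methylene blue near 612–632 nm has been attributed over the
years to dimers, vibronic progression, higher excited states, mesomerism and
trimers. `dyespec` implements the quantitative machinery needed to test the
two surviving explanations jointly:

1. **Franck–Condon vibronic progression** of the monomer. Both electronic
   surfaces are harmonic about their own minima (adiabatic-Hessian,
   independent-mode picture). For each mode with ground/excited frequencies
   ω″, ω′ and dimensionless displacement Δ (Huang–Rhys factor S = Δ²/2), the
   1-D overlaps ⟨χ″_m|χ′_n⟩ are evaluated by a stable two-index recursion
   seeded with the closed-form ⟨0|0⟩, Boltzmann-weighted over initial states
   at finite temperature, and broadened with unit-area Gaussians.

2. **Monomer–dimer equilibrium superposition.** With dimerization constant
   K_D = [D]/[M]² and total dye concentration C_i,

       [M] = (−1 + √(1 + 8 K_D C_i)) / (4 K_D),   [D] = (C_i − [M]) / 2,

   and the solution absorbance is

       A(ν) = ε_M [M] A_M(ν) + ε_D [D] A_DA(ν) + ε_D [D] A_DB(ν),

   where A_M is the monomer band and A_DA/A_DB the bright upper-exciton
   bands of the parallel and antiparallel stacked (H-aggregate) dimer
   conformers — the lower excitons are dark. Nonlinear least squares over a
   concentration series recovers (K_D, ε_M, ε_D).

3. **Classical input/output nanocavity model.** The plasmonic mode and the
   molecular transitions are damped oscillators; the cavity susceptibility

       χ(E) = [ω_c − E − iκ/2 − Σ_j g_j²/(ω_j − E − iγ_j/2)]⁻¹

   yields extinction/scattering spectra, upper/lower polariton positions,
   Rabi splitting, and the UP/LP height asymmetry produced when the vibronic
   shoulder is included as a second transition.

A seeded synthetic-data module generates every input the pipeline needs
(vibronic systems, dimer bands, noisy dilution series with an exact
794-in-1000 transfer ratio, cavity fixtures), so the whole analysis runs
without quantum-chemistry or spectrometer inputs.

## Worked example

```python
from dyespec import (make_meb_monomer, meb_like_monomer_spectrum,
                     detect_peaks, speciate)

system = make_meb_monomer()          # 0-0 at 2.14 eV, modes 454/510 cm^-1
spec = meb_like_monomer_spectrum(system.e_adiabatic, system.modes,
                                 system.temperature, width=0.022)
peaks = detect_peaks(spec)
print(f"peak {peaks.peaks[0].energy_ev:.3f} eV, "
      f"shoulder {peaks.shoulders[0].energy_ev:.3f} eV")

sp = speciate(k_d=1000.0, c_i=5e-4)
print(f"[M] = {sp.monomer_conc:.4e} M, [D] = {sp.dimer_conc:.4e} M")
```

prints

```
peak 2.140 eV, shoulder 2.206 eV
[M] = 3.0902e-04 M, [D] = 9.5492e-05 M
```

i.e. the synthetic monomer reproduces the characteristic lineshape — a
dominant 0→0 band with a single vibronic shoulder ~65 meV above it — and at
K_D = 1000 M⁻¹, C_i = 500 µM roughly 38 % of the dye is bound in dimers.

The same stages are available from a shell:

```
dyespec synth --outdir fixtures --seed 1       # complete input fixture tree
dyespec fit-kd --manifest fixtures/series_manifest.csv \
    --monomer fixtures/monomer_basis.csv \
    --dimer-a fixtures/dimer_parallel.csv \
    --dimer-b fixtures/dimer_antiparallel.csv --out fit.json
dyespec cavity --mode inout --report polaritons.json
dyespec run --outdir pipeline_out                # fcspec -> mix -> peaks -> cavity
```

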