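# Methods

This note records the models behind `dyespec`, the defaults that matter,
the numerical choices, and what the synthetic data do and do not emulate.

## Vibronic model

Absorption lineshapes are computed in the time-independent Franck–Condon
picture with both electronic surfaces expanded harmonically about their own
minima (adiabatic Hessian). Modes are independent: each ground-state normal
mode pairs with exactly one excited-state mode that may differ in frequency
(distortion) and equilibrium position (displacement). The mode-mixing
(Duschinsky) rotation is fixed to identity. This is deliberate: the
mechanistic statements the package supports are mode-by-mode (a 0→0 origin
plus one-quantum sidebands of two skeletal modes near 454 and 510 cm⁻¹),
and the `thermal_stick_spectrum` signature reserves a `rotation` argument
so a full multimode treatment can be added without breaking the API.
Herzberg–Teller intensity borrowing and anharmonicity are out of scope.

### 1-D overlaps

The overlap ⟨χ″_m|χ′_n⟩ of two displaced, distorted oscillator eigenstates
is evaluated by a two-index recursion derived from the ladder-operator
relations connecting the two oscillators. With λ = √(ω″/ω′),
μ± = (λ ± 1/λ)/2, and δ₁ = Δ/√2, δ₂ = Δ√(ω′/ω″)/√2 (Δ is the displacement
in ground-state dimensionless coordinates):

    I(0,0) = √(2√(ω″ω′)/(ω″+ω′)) · exp(−Δ² ω′ / (2(ω″+ω′)))
    I(0,n) = [ −μ₊μ₋√(n−1) I(0,n−2) − (δ₂+μ₋δ₁) I(0,n−1) ] / (√n μ₊²)
    I(m,n) = [ μ₊√n I(m−1,n−1) + μ₊μ₋√(m−1) I(m−2,n)
               + (δ₁−μ₋δ₂) I(m−1,n) ] / (√m μ₊²)

The recursion divides only by μ₊² ≥ 1, so it is stable for all frequency
ratios, and it reduces exactly to δ_mn (identical oscillators) and to the
Poisson progression |⟨0|n⟩|² = e^(−S)Sⁿ/n!, S = Δ²/2 (equal frequencies).
The test suite checks it against direct quadrature of explicit Hermite
wavefunctions to 1e-8 over m,n ≤ 6, ω′/ω″ ∈ [0.5, 2], |Δ| ≤ 3; in practice
agreement is at machine precision. Overlap signs follow from this seed and
recursion: ⟨0|1⟩ carries the sign of −Δ, ⟨1|0⟩ of +Δ, and the exchange
symmetry is I(m,n; ω″,ω′,Δ) = I(n,m; ω′,ω″,−Δ√(ω′/ω″)).

### Thermal enumeration

Initial states are enumerated over ground-surface modes with exact
geometric-ladder Boltzmann populations (kB = 8.617333262e-5 eV/K). Defaults:
initial quanta ≤ 2 per mode (for modes ≥ 400 cm⁻¹ at 300 K the m = 3
population is < 0.1 %), final quanta ≤ 8, relative intensity floor 1e-6 of
the strongest line. A guard rejects enumerations beyond 10⁶ candidate
lines. Line energies are e₀₀ + Σ(n_jω′_j − m_jω″_j) with
1 cm⁻¹ = 1.239842e-4 eV, consistent with hc = 1239.8420 eV·nm used for
nm↔eV conversion. Reported energies are rounded half-up to 2 decimals (eV)
or integers (meV), the precision at which such values are conventionally
printed.

### Broadening and peak/shoulder reading

Sticks are convolved with unit-area Gaussians; the 0.022 eV width is
interpreted as the standard deviation by default with a `width_kind="fwhm"`
switch, since width conventions vary between codes. Peak/shoulder detection
smooths with a Savitzky–Golay filter (window ≈ 5× the smoothing length,
cubic); peaks are strict local maxima above small height/prominence floors
(1e-3 and 1e-4 of the maximum) that exist only to suppress the filter's
flank ringing. Shoulder candidates are local minima of the smoothed second
derivative (negative-curvature lobes) not coinciding with a resolved peak,
scored by the dimensionless curvature −y″·(smoothing)²/max|y| and kept
above a threshold (default 0.02, chosen so a single Gaussian yields no
shoulder while the characteristic main-band-plus-sideband doublet yields
exactly one).

## Equilibrium superposition

Speciation solves K_D = [D]/[M]² with mass balance [M] + 2[D] = C_i. The
closed-form root is evaluated in the rationalized form 2C_i/(1+√(1+8K_DC_i))
and switched to a 4-term binomial series below K_D·C_i = 1e-8; both
branches agree to machine precision at the switch and mass balance holds to
1e-12 relative over many decades. The composite spectrum applies the full
dimer concentration [D] to each conformer band, taken literally from the
defining superposition; `split_conformers=True` halves each factor, the
natural reading when the two conformers are equally populated. The default
is the literal form.

K_D has no blessed default in the literature sense; the synthetic generator
uses an explicitly arbitrary 2.0e3 M⁻¹. The fit parameterizes log₁₀K_D to
keep it positive and restarts from three initial K_D guesses spread over
two decades (Levenberg–Marquardt, ftol = xtol = 1e-14); it is deterministic
given data and guesses. Identifiability comes from the nonlinearity of
[M](C_i): with ≥ 3 distinct concentrations the three parameters are
separable, and with 8-point / 1 % noise series the median K_D error is
below 1 % in practice.

## Nanocavity model

The cavity (energy ω_c, full linewidth κ) and each molecular transition
(ω_j, full linewidth γ_j, coupling g_j) are damped oscillators; all
linewidths are FULL widths and enter the complex frequencies as /2 — this
is stated prominently because half- versus full-width conventions are the
main reproducibility hazard in such models. Three response channels are
exposed:

- `extinction` (default): the absorptive quadrature Im χ, which reduces to
  a Lorentzian of FWHM κ for the bare cavity;
- `scattering`: dark-field-like |χ|²;
- `inout`: the one-port input/output extinction 1 − |r|², r = 1 + iκ_eχ,
  with κ_e = radiative_fraction·κ (default 1).

A subtlety worth recording: with the cavity exactly resonant with the 0→0
transition and a weaker vibronic transition detuned above it, the cavity
response channels (Im χ, |χ|²) always make the LOWER polariton the more
intense peak — the lossless 3×3 eigenvector analysis gives the LP a photon
fraction of ~0.52 against ~0.43 for the UP, because the upper transition
pushes the UP further from the cavity. The experimentally familiar
opposite asymmetry (stronger UP, weaker LP with a high-energy shoulder)
appears in the radiated channel: with a predominantly radiative plasmonic
linewidth, 1 − |r|² measures the power dissipated in the molecular
transitions, the UP sits closer to the vibronic absorber, and the LP's
larger coherent re-emission is subtracted. The `inout` channel reproduces
all three qualitative signatures simultaneously — UP/LP height ratio ≈ 1.10
versus exactly 1 for the single-transition system, a weak high-energy
shoulder on the LP, and a splitting enlarged by the second transition
(≈ 216 vs 175 meV with the default fixture) — and is the channel used for
those comparisons.

The coupling of the vibronic transition is scaled as g₀₀·√(I_vib/I₀₀) from
the Franck–Condon intensities (transition dipole ∝ √intensity), a modelling
choice rather than a derived result.

## Synthetic data: what it emulates, and what it does not

The generators produce a methylene-blue-like study system: monomer 0→0 at
2.14 eV with modes 25/27 at 454/510 cm⁻¹ at 300 K; bright H-aggregate dimer
bands at 2.25 eV (parallel) and 2.23 eV (antiparallel) with dark lower
excitons; dilution ladders starting at 400.5 µM with the exact
794/(794+206) = 0.794 transfer ratio; and a nanocavity resonant with the
solution-band 0→0 at 1.87 eV with the vibronic transition 56 meV above it
(a printed energy scale reused as a stand-in spacing). Multiplicative
Gaussian noise (default 1 % relative) emulates the dominant
path-length/baseline error mode of cuvette measurements; an additive offset
channel exists but is off by default. All generation is driven by numpy's
PCG64 generator; a fixed seed gives byte-identical outputs.

Numeric defaults that are *not* printed literature values — the mode
displacements, molar absorptivity scales, K_D, and the cavity linewidths
and couplings — live in `dyespec.synthetic.ARBITRARY_DEFAULTS`, explicitly
labeled as invented. Two were calibrated once, at design time, to the
qualitative geometry the system is known to show and not revisited:

- mode displacement Δ = 0.6 per mode (S = 0.18). At the 0.022 eV width,
  Δ = 0.7 already resolves the sideband into a second peak; Δ = 0.6 yields
  the characteristic single peak plus one shoulder ~65 meV above it.
- cavity κ = 0.12 eV, γ₀₀ = 0.06 eV, γ_vib = 0.08 eV, g₀₀ = 0.10 eV: a
  resolved doublet with one LP shoulder in the radiated channel.

What the synthetic data deliberately do not emulate: electronic-structure
energetics (all adiabatic energies are inputs), Duschinsky mixing,
spectrometer filter-switch discontinuities, trimers or higher aggregates,
and host–guest binding equilibria. Passing tests therefore demonstrate the
correctness of the spectral machinery and parameter recovery under the
stated noise model — not the accuracy of any quantum-chemistry prediction
for the real dye.

## Degenerate inputs and guards

Zero-mode systems produce a pure 0→0 line; T = 0 uses exact ground-state
populations; K_D = 0 gives the monomer-only limit; zero oscillator
linewidths are rejected (poles on the real axis); resampling never
extrapolates; spectra must have strictly increasing finite grids of length
≥ 2. Problem sizes used by the shipped analyses (grids of a few hundred to
a few thousand points, 20-seed recovery ensembles) keep the full test suite
and the acceptance script within seconds on one CPU.
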