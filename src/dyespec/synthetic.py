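"""Seeded generators for every input the pipeline consumes.

The generators emulate a methylene-blue-like system: a monomer with its 0-0
band at 2.14 eV and two active vibrational modes near 454 and 510 cm^-1
whose combined 0->1 lines form the vibronic shoulder; H-aggregate dimer
bands at 2.25 eV (parallel stacking) and 2.23 eV (antiparallel) whose lower
exciton is dark and therefore absent from absorption; dilution series
starting at 400.5 uM with an exact 0.794 transfer ratio; and a
nanoparticle-on-mirror-like cavity resonant with the 0-0 transition.

Every numeric default that is NOT a printed literature value (mode
displacements, molar absorptivity scales, the dimerization constant, cavity
linewidths and couplings) lives in :data:`ARBITRARY_DEFAULTS`, clearly
marked as invented, so no made-up number masquerades as a measured one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dimer import concentration_series_spectra
from .franck_condon import (HarmonicMode, VibronicSystem,
                            meb_like_monomer_spectrum, thermal_stick_spectrum)
from .polariton import CavityModel, TransitionOscillator
from .spectra import Spectrum, make_grid

#: Invented illustrative defaults — ARBITRARY, not literature values.
#: Chosen once so the synthetic system reproduces the qualitative geometry
#: of a methylene-blue-like spectrum (single dominant 0-0 peak with one
#: vibronic shoulder; resolved, asymmetric polariton doublet).
ARBITRARY_DEFAULTS: dict[str, float] = {
    "mode_displacement": 0.6,      # dimensionless Delta per mode (S = 0.18)
    "k_d": 2.0e3,                  # M^-1 dimerization constant
    "eps_m": 5.0e4,                # monomer molar absorptivity scale
    "eps_d": 3.0e4,                # dimer molar absorptivity scale
    "cavity_kappa": 0.12,          # eV, cavity full linewidth
    "transition_gamma": 0.06,      # eV, full linewidth of the 0-0 line
    "transition_gamma_vib": 0.08,  # eV, full linewidth of the vibronic line
    "g_00": 0.10,                  # eV, cavity coupling of the 0-0 line
}

#: Printed reference values the generators are anchored to.
E00_MONOMER_EV = 2.14
MODE_FREQS_CM1 = (454.0, 510.0)
MODE_INDICES = (25, 27)
DIMER_BAND_EV = {"parallel": 2.25, "antiparallel": 2.23}
GAUSS_WIDTH_EV = 0.022
TEMPERATURE_K = 300.0
DILUTION_C0_M = 400.5e-6
DILUTION_RATIO = 0.794           # 794 uL into 206 uL of water
VIBRONIC_OFFSET_EV = 0.056       # stand-in spacing for the shoulder line


@dataclass(frozen=True)
class GeneratorConfig:
    """Reproducibility contract for the generators: a fixed seed yields
    byte-identical outputs (numpy PCG64 generator)."""

    seed: int = 0
    noise_sigma_rel: float = 0.01
    grid_min: float = 1.70   # eV
    grid_max: float = 2.60   # eV
    grid_spacing: float = 0.002
    dilution_c0: float = DILUTION_C0_M
    dilution_ratio: float = DILUTION_RATIO
    dilution_steps: int = 7  # n = 0..steps inclusive -> 8 spectra

    def __post_init__(self) -> None:
        if self.noise_sigma_rel < 0:
            raise ValueError("noise level must be non-negative")
        if not 0.0 < self.dilution_ratio < 1.0:
            raise ValueError("transfer fraction must lie in (0, 1)")

    def grid(self) -> np.ndarray:
        return make_grid(self.grid_min, self.grid_max, self.grid_spacing)


def make_meb_monomer(*, displacement: float | None = None,
                     temperature: float = TEMPERATURE_K) -> VibronicSystem:
    """Methylene-blue-like monomer: 0-0 at 2.14 eV, modes 25 and 27 at 454
    and 510 cm^-1 (equal ground/excited frequencies), arbitrary default
    displacement per mode."""
    d = ARBITRARY_DEFAULTS["mode_displacement"] if displacement is None \
        else displacement
    modes = tuple(HarmonicMode(index=i, freq_ground=f, freq_excited=f,
                               displacement=d)
                  for i, f in zip(MODE_INDICES, MODE_FREQS_CM1))
    return VibronicSystem(e_adiabatic=E00_MONOMER_EV, modes=modes,
                          temperature=temperature)


def make_monomer_spectrum(config: GeneratorConfig | None = None, *,
                          displacement: float | None = None) -> Spectrum:
    """Broadened monomer vibronic spectrum on the configured grid,
    normalized to unit area (a molar-absorptivity basis shape)."""
    config = config or GeneratorConfig()
    system = make_meb_monomer(displacement=displacement)
    spec = meb_like_monomer_spectrum(
        system.e_adiabatic, system.modes, system.temperature, GAUSS_WIDTH_EV,
        grid=config.grid())
    area = spec.area()
    return Spectrum(spec.energies, spec.values / area,
                    label="monomer basis", provenance="synthetic")


def make_dimer_bands(conformer: str, *, width: float = GAUSS_WIDTH_EV,
                     grid: np.ndarray | None = None) -> Spectrum:
    """Unit-area Gaussian band of one H-aggregate dimer conformer.

    Only the bright upper exciton absorbs (the lower exciton is dark), so
    each conformer contributes a single band: 2.25 eV for parallel, 2.23 eV
    for antiparallel stacking.
    """
    if conformer not in DIMER_BAND_EV:
        raise ValueError(f"unknown conformer {conformer!r}; expected one of "
                         f"{sorted(DIMER_BAND_EV)}")
    center = DIMER_BAND_EV[conformer]
    if grid is None:
        grid = GeneratorConfig().grid()
    z = (grid - center) / width
    vals = np.exp(-0.5 * z * z) / (width * math.sqrt(2.0 * math.pi))
    return Spectrum(grid, vals, label=f"{conformer} dimer band",
                    provenance="synthetic")


def dilution_concentrations(config: GeneratorConfig) -> np.ndarray:
    """c_n = c0 * ratio^n for n = 0..dilution_steps (strictly decreasing)."""
    n = np.arange(config.dilution_steps + 1)
    return config.dilution_c0 * config.dilution_ratio ** n


def make_dilution_series(config: GeneratorConfig | None = None, *,
                         k_d: float | None = None,
                         eps_m: float | None = None,
                         eps_d: float | None = None
                         ) -> list[tuple[float, Spectrum]]:
    """Noisy concentration series of composite solution spectra.

    Spectra follow the monomer-dimer superposition at the configured K_D
    with multiplicative Gaussian noise of ``noise_sigma_rel``; deterministic
    per seed.
    """
    config = config or GeneratorConfig()
    k_d = ARBITRARY_DEFAULTS["k_d"] if k_d is None else k_d
    eps_m = ARBITRARY_DEFAULTS["eps_m"] if eps_m is None else eps_m
    eps_d = ARBITRARY_DEFAULTS["eps_d"] if eps_d is None else eps_d
    grid = config.grid()
    a_m = make_monomer_spectrum(config)
    a_da = make_dimer_bands("parallel", grid=grid)
    a_db = make_dimer_bands("antiparallel", grid=grid)
    concs = dilution_concentrations(config)
    clean = concentration_series_spectra(k_d, eps_m, eps_d, concs,
                                         a_m, a_da, a_db)
    rng = np.random.default_rng(config.seed)
    out = []
    for c, spec in zip(concs, clean):
        noise = 1.0 + config.noise_sigma_rel * rng.standard_normal(
            spec.values.size)
        out.append((float(c), Spectrum(grid, spec.values * noise,
                                       label=f"dilution c={c:.4g} M",
                                       provenance="synthetic")))
    return out


def vibronic_intensity_ratio(system: VibronicSystem | None = None) -> float:
    """Intensity of the combined vibronic-shoulder lines relative to the
    0-0 line, from the Franck-Condon stick spectrum (lines with one quantum
    of final-state excitation vs. the pure 0-0 line, at T = 0)."""
    system = system or make_meb_monomer(temperature=0.0)
    if system.temperature != 0.0:
        system = VibronicSystem(system.e_adiabatic, system.modes, 0.0,
                                system.intensity_scale)
    sticks = thermal_stick_spectrum(system)
    i00 = ivib = 0.0
    for line in sticks.lines:
        total_final = sum(n for _, _, n in line.assignment)
        if total_final == 0:
            i00 += line.intensity
        elif total_final == 1:
            ivib += line.intensity
    if i00 == 0:
        raise ValueError("0-0 line missing from stick spectrum")
    return ivib / i00


def make_cavity_fixture(include_vibronic: bool, *,
                        omega_00: float = 1.87) -> CavityModel:
    """Nanocavity resonant with the 0-0 transition, with or without the
    vibronic-shoulder transition.

    The 0-0 energy defaults to 1.87 eV (the solution absorption maximum);
    the vibronic transition sits 56 meV above it, with its coupling scaled
    by the square root of the Franck-Condon intensity ratio (transition
    dipole scales as the square root of intensity).
    """
    kappa = ARBITRARY_DEFAULTS["cavity_kappa"]
    gamma = ARBITRARY_DEFAULTS["transition_gamma"]
    g00 = ARBITRARY_DEFAULTS["g_00"]
    transitions = [TransitionOscillator(omega=omega_00, gamma=gamma, g=g00)]
    if include_vibronic:
        gvib = g00 * math.sqrt(vibronic_intensity_ratio())
        transitions.append(TransitionOscillator(
            omega=omega_00 + VIBRONIC_OFFSET_EV,
            gamma=ARBITRARY_DEFAULTS["transition_gamma_vib"], g=gvib))
    return CavityModel(omega_c=omega_00, kappa=kappa,
                       transitions=tuple(transitions))
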