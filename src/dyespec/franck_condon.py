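"""Finite-temperature Franck-Condon stick spectra for harmonic surfaces.

Both electronic surfaces are expanded harmonically about their own minima
(adiabatic-Hessian picture) and the normal modes are treated as independent:
each ground-state mode pairs with exactly one excited-state mode that may
differ in frequency (distortion) and equilibrium position (displacement).
The mode-mixing (Duschinsky) rotation is fixed to identity; the
``thermal_stick_spectrum`` signature reserves a ``rotation`` argument so a
full multimode treatment can be added without an API change.

The 1-D overlap ⟨χ″_m|χ′_n⟩ between oscillators of frequency ω″ (initial,
ground surface) and ω′ (final, excited surface), whose minima are separated
by a dimensionless displacement Δ expressed in ground-state coordinates
(Huang-Rhys factor S = Δ²/2 when ω″ = ω′), is evaluated with a stable
two-index recursion derived from the ladder-operator relations between the
two oscillators, seeded by the closed-form ⟨0|0⟩:

    |⟨0|0⟩|² = 2√(ω′ω″)/(ω′+ω″) · exp(−Δ² ω′/(ω″+ω′))

Sign convention: overlaps are real; ⟨0|1⟩ carries the sign of −Δ and ⟨1|0⟩
the sign of +Δ. The exchange symmetry is

    fc_overlap_1d(m, n, ω″, ω′, Δ) == fc_overlap_1d(n, m, ω′, ω″, −Δ·√(ω′/ω″))

because the displacement argument is always expressed in the coordinates of
the initial (first-frequency) oscillator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import CM1_TO_EV, KB_EV_PER_K
from .spectra import Spectrum, StickLine, StickSpectrum, convolve_gaussian, make_grid

MAX_QUANTA = 64  # recursion cap; far beyond anything needed in scope
MAX_LINES = 1_000_000


# ---------------------------------------------------------------------------
# model types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonicMode:
    """One vibrational normal mode shared (up to distortion) by both surfaces.

    ``displacement`` is the dimensionless shift Δ between the two minima in
    ground-state dimensionless coordinates.
    """

    index: int
    freq_ground: float  # cm^-1
    freq_excited: float  # cm^-1
    displacement: float

    def __post_init__(self) -> None:
        if self.freq_ground <= 0 or self.freq_excited <= 0:
            raise ValueError("mode frequencies must be positive")
        if not math.isfinite(self.displacement):
            raise ValueError("displacement must be finite")

    @property
    def huang_rhys(self) -> float:
        """S = Δ²/2 (exact for equal frequencies)."""
        return 0.5 * self.displacement ** 2


@dataclass(frozen=True)
class VibronicSystem:
    """Adiabatic 0-0 energy plus a list of active modes at a temperature."""

    e_adiabatic: float  # eV
    modes: tuple[HarmonicMode, ...] = ()
    temperature: float = 300.0  # K
    intensity_scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "modes", tuple(self.modes))
        if self.e_adiabatic <= 0:
            raise ValueError("adiabatic energy must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")


# ---------------------------------------------------------------------------
# 1-D overlaps
# ---------------------------------------------------------------------------

def fc_overlap_table(m_max: int, n_max: int, freq_ground: float,
                     freq_excited: float, displacement: float) -> np.ndarray:
    """Table of overlaps ⟨χ″_m|χ′_n⟩ for m ≤ m_max, n ≤ n_max."""
    if m_max < 0 or n_max < 0:
        raise ValueError("quanta must be non-negative")
    if m_max > MAX_QUANTA or n_max > MAX_QUANTA:
        raise ValueError(f"quanta beyond recursion cap {MAX_QUANTA}")
    if freq_ground <= 0 or freq_excited <= 0:
        raise ValueError("frequencies must be positive")

    wg, we, d1 = float(freq_ground), float(freq_excited), float(displacement)
    lam = math.sqrt(wg / we)
    mu_p = 0.5 * (lam + 1.0 / lam)
    mu_m = 0.5 * (lam - 1.0 / lam)
    delta1 = d1 / math.sqrt(2.0)
    delta2 = d1 * math.sqrt(we / wg) / math.sqrt(2.0)

    I = np.zeros((m_max + 1, n_max + 1))
    I[0, 0] = math.sqrt(2.0 * math.sqrt(wg * we) / (wg + we)) * \
        math.exp(-0.5 * d1 * d1 * we / (wg + we))

    # first row: lower n with m = 0
    for n in range(1, n_max + 1):
        acc = -(delta2 + mu_m * delta1) * I[0, n - 1]
        if n >= 2:
            acc -= mu_m * mu_p * math.sqrt(n - 1) * I[0, n - 2]
        I[0, n] = acc / (math.sqrt(n) * mu_p ** 2)

    # subsequent rows: lower m
    for m in range(1, m_max + 1):
        for n in range(0, n_max + 1):
            acc = (delta1 - mu_m * delta2) * I[m - 1, n]
            if n >= 1:
                acc += mu_p * math.sqrt(n) * I[m - 1, n - 1]
            if m >= 2:
                acc += mu_m * mu_p * math.sqrt(m - 1) * I[m - 2, n]
            I[m, n] = acc / (math.sqrt(m) * mu_p ** 2)
    return I


def fc_overlap_1d(m: int, n: int, freq_ground: float, freq_excited: float,
                  displacement: float) -> float:
    """Overlap amplitude ⟨χ″_m|χ′_n⟩ of two displaced, distorted harmonic
    oscillator eigenstates; |amplitude| ≤ 1."""
    if m < 0 or n < 0:
        raise ValueError("quanta must be non-negative")
    return float(fc_overlap_table(m, n, freq_ground, freq_excited,
                                  displacement)[m, n])


def huang_rhys_progression(S: float, freq: float, e00: float,
                           n_max: int) -> StickSpectrum:
    """Zero-temperature, equal-frequency Poisson progression.

    Lines at ``e00 + n * freq`` (freq in cm^-1, energies in eV) with
    intensities e^(−S) Sⁿ/n! for n = 0..n_max.
    """
    if S < 0:
        raise ValueError("Huang-Rhys factor must be non-negative")
    if n_max < 0:
        raise ValueError("n_max must be non-negative")
    lines = []
    for n in range(n_max + 1):
        inten = math.exp(-S) * S ** n / math.factorial(n) if S > 0 else (1.0 if n == 0 else 0.0)
        lines.append(StickLine(e00 + n * freq * CM1_TO_EV, inten,
                               ((0, 0, n),)))
    return StickSpectrum(tuple(lines))


# ---------------------------------------------------------------------------
# thermal enumeration
# ---------------------------------------------------------------------------

def _mode_populations(freq_cm1: float, temperature: float,
                      m_cap: int) -> np.ndarray:
    """Boltzmann populations of the first m_cap+1 levels of one ground-state
    mode, normalized over the full (untruncated) oscillator ladder."""
    if temperature == 0:
        p = np.zeros(m_cap + 1)
        p[0] = 1.0
        return p
    x = freq_cm1 * CM1_TO_EV / (KB_EV_PER_K * temperature)
    m = np.arange(m_cap + 1)
    return np.exp(-m * x) * (1.0 - math.exp(-x))


def thermal_stick_spectrum(system: VibronicSystem, *,
                           max_initial_quanta: int = 2,
                           max_final_quanta: int = 8,
                           intensity_floor: float = 1e-6,
                           rotation: None = None) -> StickSpectrum:
    """Finite-temperature Franck-Condon stick spectrum.

    Initial states are enumerated over the ground-surface modes with
    Boltzmann weights at ``system.temperature``; final states up to
    ``max_final_quanta`` per mode. Line energy is
    ``e_adiabatic + Σ_j (n_j ω′_j − m_j ω″_j)`` (in eV) and line intensity is
    the Boltzmann weight times the product of squared 1-D overlaps, times
    ``intensity_scale``. Lines weaker than ``intensity_floor`` relative to
    the strongest line are dropped.

    ``rotation`` is reserved for a future Duschinsky treatment and must be
    None.
    """
    if rotation is not None:
        raise NotImplementedError("mode-mixing rotations are not supported")
    if max_initial_quanta < 0 or max_final_quanta < 0:
        raise ValueError("quanta caps must be non-negative")
    if intensity_floor < 0:
        raise ValueError("intensity floor must be non-negative")

    modes = system.modes
    if not modes:
        return StickSpectrum((StickLine(system.e_adiabatic,
                                        system.intensity_scale, ()),))

    n_lines = (max_initial_quanta + 1) ** len(modes) * \
              (max_final_quanta + 1) ** len(modes)
    if n_lines > MAX_LINES:
        raise ValueError(
            f"{n_lines} candidate lines exceed the {MAX_LINES} guard; "
            "raise intensity_floor or lower the quanta caps")

    tables = [fc_overlap_table(max_initial_quanta, max_final_quanta,
                               md.freq_ground, md.freq_excited,
                               md.displacement) for md in modes]
    pops = [_mode_populations(md.freq_ground, system.temperature,
                              max_initial_quanta) for md in modes]
    eg = np.array([md.freq_ground * CM1_TO_EV for md in modes])
    ee = np.array([md.freq_excited * CM1_TO_EV for md in modes])

    raw: list[StickLine] = []
    initial_states = itertools.product(range(max_initial_quanta + 1),
                                       repeat=len(modes))
    for mstate in initial_states:
        w = math.prod(pops[j][mj] for j, mj in enumerate(mstate))
        if w == 0.0:
            continue
        for nstate in itertools.product(range(max_final_quanta + 1),
                                        repeat=len(modes)):
            fc2 = math.prod(tables[j][mstate[j], nstate[j]] ** 2
                            for j in range(len(modes)))
            inten = w * fc2 * system.intensity_scale
            if inten == 0.0:
                continue
            energy = system.e_adiabatic + float(
                np.dot(nstate, ee) - np.dot(mstate, eg))
            assignment = tuple((modes[j].index, mstate[j], nstate[j])
                               for j in range(len(modes)))
            raw.append(StickLine(energy, inten, assignment))

    if not raw:
        return StickSpectrum(())
    peak = max(l.intensity for l in raw)
    kept = tuple(l for l in raw if l.intensity >= intensity_floor * peak)
    return StickSpectrum(tuple(sorted(kept, key=lambda l: l.energy)))


def meb_like_monomer_spectrum(e00: float, modes, temperature: float,
                              width: float, *, grid: np.ndarray | None = None,
                              width_kind: str = "sigma",
                              grid_spacing: float | None = None) -> Spectrum:
    """Broadened vibronic absorption spectrum of a monomeric dye.

    Composition of :func:`thermal_stick_spectrum` and Gaussian convolution.
    With the methylene-blue-like defaults (0-0 at 2.14 eV, modes near 454
    and 510 cm^-1, 300 K, 0.022 eV width) the result shows one global peak
    at the 0-0 energy and a single vibronic shoulder 40-70 meV above it.
    """
    system = VibronicSystem(e_adiabatic=e00, modes=tuple(modes),
                            temperature=temperature)
    sticks = thermal_stick_spectrum(system)
    if grid is None:
        energies = sticks.energies
        lo, hi = float(energies.min()), float(energies.max())
        spacing = grid_spacing if grid_spacing is not None else width / 10.0
        grid = make_grid(lo - 6 * width, hi + 6 * width, spacing)
    return convolve_gaussian(sticks, width, grid, width_kind=width_kind,
                             label="monomer vibronic spectrum")
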