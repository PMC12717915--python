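"""Classical input/output model of a plasmonic nanocavity coupled to
molecular transitions.

The cavity mode and each molecular transition are damped oscillators
(Lorentzians). The steady-state cavity response to a weak drive at photon
energy E is the complex susceptibility

    χ(E) = [ ω_c − E − iκ/2 − Σ_j g_j² / (ω_j − E − iγ_j/2) ]⁻¹

where ω_c and κ are the cavity energy and FULL linewidth, and each
transition j contributes energy ω_j, full linewidth γ_j and coupling g_j
(all in eV). Linewidths are full widths (FWHM-type); they enter the complex
frequencies as /2, which is the main convention hazard in this model and is
therefore stated here once and used everywhere.

Extinction is the absorptive quadrature of χ (the imaginary part with the
sign that reduces to a Lorentzian absorption profile in the uncoupled
limit); a dark-field-like scattering mode |χ|² is available behind a flag. With one resonant transition the extinction doublet is the
symmetric Rabi splitting of a two-level system; adding a second, detuned
(vibronic) transition makes the upper polariton more intense than the lower
one and widens the splitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .spectra import PeakSet, Spectrum, detect_peaks


@dataclass(frozen=True)
class TransitionOscillator:
    """A molecular transition as a Lorentzian oscillator (energies in eV).

    ``gamma`` is the FULL linewidth; ``g`` the coupling to the cavity mode.
    """

    omega: float
    gamma: float
    g: float

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("transition energy must be positive")
        if self.gamma <= 0:
            raise ValueError("transition linewidth must be positive "
                             "(zero puts a pole on the real axis)")
        if self.g < 0:
            raise ValueError("coupling must be non-negative")


@dataclass(frozen=True)
class CavityModel:
    """Cavity mode (energy ``omega_c``, full linewidth ``kappa``) plus the
    molecular transitions coupled to it."""

    omega_c: float
    kappa: float
    transitions: tuple[TransitionOscillator, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "transitions", tuple(self.transitions))
        if self.omega_c <= 0:
            raise ValueError("cavity energy must be positive")
        if self.kappa <= 0:
            raise ValueError("cavity linewidth must be positive")


@dataclass(frozen=True)
class PolaritonReport:
    """Upper/lower polariton positions, splitting and height asymmetry."""

    up_energy: float
    lp_energy: float
    splitting: float
    up_height: float
    lp_height: float
    asymmetry: float  # up_height / lp_height
    n_peaks: int


def cavity_susceptibility(model: CavityModel,
                          energy: "float | np.ndarray") -> "complex | np.ndarray":
    """Complex cavity susceptibility χ(E); finite for all real E."""
    e = np.asarray(energy, dtype=float)
    denom = model.omega_c - e - 0.5j * model.kappa
    for t in model.transitions:
        if t.g > 0:
            denom = denom - t.g ** 2 / (t.omega - e - 0.5j * t.gamma)
    chi = 1.0 / denom
    return chi if np.ndim(energy) else complex(chi)


def extinction_spectrum(model: CavityModel, grid: np.ndarray, *,
                        mode: str = "extinction",
                        radiative_fraction: float = 1.0,
                        normalize: bool = True) -> Spectrum:
    """Optical response of the coupled system on an energy grid.

    Modes
    -----
    ``"extinction"`` (default)
        The absorptive quadrature of χ. With the e^{+iωt} sign convention
        used in :func:`cavity_susceptibility` (denominator ω_c − E − iκ/2)
        this is +Im χ; for the bare cavity it is the Lorentzian
        (κ/2)/((ω_c−E)² + κ²/4).
    ``"scattering"``
        Dark-field-like |χ|².
    ``"inout"``
        One-port input/output extinction 1 − |r|² with r = 1 + iκ_e χ and
        external coupling κ_e = ``radiative_fraction`` · κ, i.e.
        2κ_e·Im χ − κ_e²·|χ|². With a fully radiative cavity
        (``radiative_fraction=1``) this is the power absorbed by the
        molecular transitions; the lower polariton's larger coherent
        re-emission is subtracted here, which is what makes the upper
        polariton the more intense one when a vibronic transition sits
        above the 0-0 line.

    Normalized to unit maximum unless ``normalize=False``.
    """
    grid = np.asarray(grid, dtype=float)
    chi = cavity_susceptibility(model, grid)
    if mode == "extinction":
        vals = np.imag(chi)
    elif mode == "scattering":
        vals = np.abs(chi) ** 2
    elif mode == "inout":
        if not 0.0 < radiative_fraction <= 1.0:
            raise ValueError("radiative_fraction must lie in (0, 1]")
        ke = radiative_fraction * model.kappa
        vals = 2.0 * ke * np.imag(chi) - ke ** 2 * np.abs(chi) ** 2
    else:
        raise ValueError("mode must be 'extinction', 'scattering' or 'inout'")
    if normalize:
        top = float(vals.max())
        if top > 0:
            vals = vals / top
    return Spectrum(grid, vals, label=f"cavity {mode}", provenance="computed")


def polariton_eigenvalues(model: CavityModel) -> tuple[complex, complex]:
    """Complex eigenvalues of the 2x2 cavity + single-transition matrix,
    ordered by descending real part. The real-part difference is the Rabi
    splitting; at resonance with kappa != gamma it is
    2*sqrt(g^2 - (kappa-gamma)^2/16)."""
    if len(model.transitions) != 1:
        raise ValueError("closed form requires exactly one transition")
    t = model.transitions[0]
    h = np.array([[model.omega_c - 0.5j * model.kappa, t.g],
                  [t.g, t.omega - 0.5j * t.gamma]])
    ev = np.linalg.eigvals(h)
    ev = sorted(ev, key=lambda z: z.real, reverse=True)
    return (complex(ev[0]), complex(ev[1]))


def analyze_polaritons(spectrum: Spectrum, *, smoothing: float = 0.005,
                       shoulder_threshold: float = 0.02) -> PolaritonReport:
    """Read UP/LP positions, splitting and height asymmetry off a spectrum.

    UP and LP are the highest- and lowest-energy resolved peaks; raises if
    fewer than two peaks are resolved (system not in the resolved-splitting
    regime).
    """
    ps = detect_peaks(spectrum, smoothing=smoothing,
                      shoulder_threshold=shoulder_threshold)
    if len(ps.peaks) < 2:
        raise ValueError("system not in resolved splitting regime "
                         f"({len(ps.peaks)} peak(s) found)")
    lp, up = ps.peaks[0], ps.peaks[-1]
    return PolaritonReport(
        up_energy=up.energy_ev, lp_energy=lp.energy_ev,
        splitting=up.energy_ev - lp.energy_ev,
        up_height=up.height, lp_height=lp.height,
        asymmetry=up.height / lp.height, n_peaks=len(ps.peaks))
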