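"""Independent numerical oracles used by the tests.

These deliberately avoid the package's own algorithms: vibrational overlaps
come from direct quadrature of explicit harmonic-oscillator wavefunctions,
and equilibrium speciation from a 1-D bracketing root finder on the defining
mass-action relation.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.polynomial.hermite import hermval
from scipy.optimize import brentq


def ho_wavefunction(n: int, omega: float, center: float,
                    x: np.ndarray) -> np.ndarray:
    """Harmonic-oscillator eigenfunction psi_n for unit mass and hbar."""
    xi = np.sqrt(omega) * (x - center)
    coeffs = np.zeros(n + 1)
    coeffs[n] = 1.0
    norm = (omega / np.pi) ** 0.25 / math.sqrt(2.0 ** n * math.factorial(n))
    return norm * hermval(xi, coeffs) * np.exp(-0.5 * xi * xi)


def fc_overlap_quadrature(m: int, n: int, freq_ground: float,
                          freq_excited: float, displacement: float,
                          n_points: int = 40001,
                          half_range: float = 30.0) -> float:
    """⟨χ″_m|χ′_n⟩ by trapezoid quadrature; displacement is the shift of the
    excited minimum in ground-state dimensionless coordinates."""
    x = np.linspace(-half_range, half_range, n_points)
    x0 = displacement / math.sqrt(freq_ground)
    return float(np.trapezoid(
        ho_wavefunction(m, freq_ground, 0.0, x) *
        ho_wavefunction(n, freq_excited, x0, x), x))


def fc_overlap_quadrature_table(m_max: int, n_max: int, freq_ground: float,
                                freq_excited: float, displacement: float,
                                n_points: int = 40001,
                                half_range: float = 30.0) -> np.ndarray:
    """All overlaps up to (m_max, n_max) from one shared quadrature grid."""
    x = np.linspace(-half_range, half_range, n_points)
    dx = x[1] - x[0]
    x0 = displacement / math.sqrt(freq_ground)
    psi_g = np.array([ho_wavefunction(m, freq_ground, 0.0, x)
                      for m in range(m_max + 1)])
    psi_e = np.array([ho_wavefunction(n, freq_excited, x0, x)
                      for n in range(n_max + 1)])
    w = np.full(x.size, dx)
    w[0] = w[-1] = dx / 2
    return (psi_g * w) @ psi_e.T


def speciate_root(k_d: float, c_i: float) -> tuple[float, float]:
    """Monomer/dimer concentrations via brentq on K_D = ((C_i−M)/2)/M²."""
    if k_d == 0:
        return c_i, 0.0

    def f(m: float) -> float:
        return k_d * m * m + 0.5 * m - 0.5 * c_i

    m = brentq(f, 0.0, c_i, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    return m, 0.5 * (c_i - m)
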