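"""Physical constants and reporting conventions.

All energies inside the package are photon energies in eV; wavelengths in nm;
vibrational frequencies in cm^-1. Conversions use a single hc value so that
nm <-> eV <-> cm^-1 round-trips are self-consistent.
"""

from __future__ import annotations

import decimal

#: hc in eV*nm (CODATA-consistent, truncated to the precision used throughout).
HC_EV_NM: float = 1239.8420

#: 1 cm^-1 in eV; equals HC_EV_NM * 1e-7.
CM1_TO_EV: float = 1.239842e-4

#: Boltzmann constant in eV/K.
KB_EV_PER_K: float = 8.617333262e-5


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, matching how band energies are
    conventionally reported (2 decimals in eV, integers in meV). Python's
    built-in round() is banker's rounding and disagrees on exact ties."""
    q = decimal.Decimal(10) ** -ndigits
    d = decimal.Decimal(repr(float(x))).quantize(
        q, rounding=decimal.ROUND_HALF_UP)
    return float(d)
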