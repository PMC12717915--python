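"""Readers and writers for the delimited-text and YAML/JSON formats the
pipeline exchanges.

Spectra travel as two-column delimited text (comma or tab, auto-detected;
decimal points only — locale commas are rejected as malformed rows). Column
one is either wavelength in nm or energy in eV, declared by the header
(``wavelength_nm`` / ``energy_ev``) or by the caller; column two is
absorbance. Written files always carry a header and a ``#`` provenance
comment. Model objects (vibronic systems, cavity models) round-trip through
YAML or JSON mappings.
"""

from __future__ import annotations

import csv
import io as _io
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from .franck_condon import HarmonicMode, VibronicSystem
from .polariton import CavityModel, TransitionOscillator
from .spectra import Spectrum, StickSpectrum, nm_to_ev

log = logging.getLogger(__name__)

_NM_NAMES = {"wavelength_nm", "nm", "wavelength"}
_EV_NAMES = {"energy_ev", "ev", "energy"}


def _split_row(line: str) -> list[str]:
    if "\t" in line:
        return [f.strip() for f in line.split("\t")]
    if "," in line:
        return [f.strip() for f in line.split(",")]
    return line.split()


def read_spectrum(path: "str | Path", units: str | None = None, *,
                  label: str | None = None,
                  provenance: str = "measured") -> Spectrum:
    """Read a two-column spectrum file.

    ``units`` ("nm" or "ev") may be omitted when the header names the first
    column. nm input is converted to an ascending eV grid.
    """
    path = Path(path)
    xs: list[float] = []
    ys: list[float] = []
    header_units = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = _split_row(line)
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, "
                                 f"got {len(fields)}")
            try:
                x, y = float(fields[0]), float(fields[1])
            except ValueError:
                if not xs and header_units is None:
                    name = fields[0].lower()
                    if name in _NM_NAMES:
                        header_units = "nm"
                    elif name in _EV_NAMES:
                        header_units = "ev"
                    else:
                        raise ValueError(
                            f"{path}:{lineno}: unrecognized header column "
                            f"{fields[0]!r} (expected wavelength_nm or "
                            "energy_ev)") from None
                    continue
                raise ValueError(
                    f"{path}:{lineno}: non-numeric row {line!r}") from None
            xs.append(x)
            ys.append(y)
    if not xs:
        raise ValueError(f"{path}: no data rows")

    units = units or header_units
    if units is None:
        raise ValueError(f"{path}: units not declared in header; pass "
                         "units='nm' or units='ev'")
    units = units.lower()
    x_arr, y_arr = np.array(xs), np.array(ys)
    if units == "nm":
        x_arr = nm_to_ev(x_arr)
    elif units != "ev":
        raise ValueError(f"unknown units {units!r}; expected 'nm' or 'ev'")

    order = np.argsort(x_arr, kind="stable")
    if not np.array_equal(order, np.arange(order.size)):
        log.warning("%s: grid not ascending in eV after conversion; sorting",
                    path)
        x_arr, y_arr = x_arr[order], y_arr[order]
    return Spectrum(x_arr, y_arr, label=label or path.stem,
                    provenance=provenance)


def write_spectrum(spectrum: Spectrum, path: "str | Path", *,
                   units: str = "ev") -> None:
    """Write a spectrum as CSV with a provenance comment and header."""
    path = Path(path)
    if units.lower() != "ev":
        raise ValueError("spectra are written on the eV grid only")
    with path.open("w") as fh:
        fh.write(f"# dyespec spectrum; provenance={spectrum.provenance}; "
                 f"label={spectrum.label}\n")
        fh.write("energy_ev,absorbance\n")
        for e, v in zip(spectrum.energies, spectrum.values):
            fh.write(f"{float(e)!r},{float(v)!r}\n")


def write_sticks(sticks: StickSpectrum, path: "str | Path") -> None:
    """Stick spectrum as CSV: energy, intensity, assignment like
    ``25:0-1|27:0-0``."""
    with Path(path).open("w") as fh:
        fh.write("# dyespec stick spectrum\n")
        fh.write("energy_ev,intensity,assignment\n")
        for line in sticks.lines:
            fh.write(f"{float(line.energy)!r},{float(line.intensity)!r},"
                     f"{line.assignment_string()}\n")


# ---------------------------------------------------------------------------
# model serialization
# ---------------------------------------------------------------------------

def vibronic_system_to_dict(system: VibronicSystem) -> dict:
    return {
        "e_adiabatic_ev": system.e_adiabatic,
        "temperature_k": system.temperature,
        "intensity_scale": system.intensity_scale,
        "modes": [{"index": m.index, "freq_ground_cm1": m.freq_ground,
                   "freq_excited_cm1": m.freq_excited,
                   "displacement": m.displacement} for m in system.modes],
    }


def vibronic_system_from_dict(d: dict) -> VibronicSystem:
    modes = tuple(HarmonicMode(index=int(m["index"]),
                               freq_ground=float(m["freq_ground_cm1"]),
                               freq_excited=float(m["freq_excited_cm1"]),
                               displacement=float(m["displacement"]))
                  for m in d.get("modes", []))
    return VibronicSystem(e_adiabatic=float(d["e_adiabatic_ev"]), modes=modes,
                          temperature=float(d.get("temperature_k", 300.0)),
                          intensity_scale=float(d.get("intensity_scale", 1.0)))


def cavity_model_to_dict(model: CavityModel) -> dict:
    return {
        "omega_c_ev": model.omega_c,
        "kappa_ev": model.kappa,
        "transitions": [{"omega_ev": t.omega, "gamma_ev": t.gamma,
                         "g_ev": t.g} for t in model.transitions],
    }


def cavity_model_from_dict(d: dict) -> CavityModel:
    transitions = tuple(TransitionOscillator(omega=float(t["omega_ev"]),
                                             gamma=float(t["gamma_ev"]),
                                             g=float(t["g_ev"]))
                        for t in d.get("transitions", []))
    return CavityModel(omega_c=float(d["omega_c_ev"]),
                       kappa=float(d["kappa_ev"]), transitions=transitions)


def _load_mapping(path: Path) -> dict:
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _dump_mapping(d: dict, path: Path) -> None:
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def load_vibronic_system(path: "str | Path") -> VibronicSystem:
    return vibronic_system_from_dict(_load_mapping(Path(path)))


def save_vibronic_system(system: VibronicSystem, path: "str | Path") -> None:
    _dump_mapping(vibronic_system_to_dict(system), Path(path))


def load_cavity_model(path: "str | Path") -> CavityModel:
    return cavity_model_from_dict(_load_mapping(Path(path)))


def save_cavity_model(model: CavityModel, path: "str | Path") -> None:
    _dump_mapping(cavity_model_to_dict(model), Path(path))


# ---------------------------------------------------------------------------
# concentration-series manifest
# ---------------------------------------------------------------------------

def write_series_manifest(series: list[tuple[float, str]],
                          path: "str | Path") -> None:
    """CSV manifest: concentration_M, spectrum_path (relative paths are
    resolved against the manifest's directory on read)."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["concentration_M", "spectrum_path"])
        for conc, sp in series:
            w.writerow([repr(float(conc)), sp])


def read_series_manifest(path: "str | Path",
                         units: str = "ev") -> list[tuple[float, Spectrum]]:
    path = Path(path)
    out = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or \
                "concentration_M" not in reader.fieldnames or \
                "spectrum_path" not in reader.fieldnames:
            raise ValueError(f"{path}: manifest needs columns "
                             "concentration_M, spectrum_path")
        for row in reader:
            sp_path = Path(row["spectrum_path"])
            if not sp_path.is_absolute():
                sp_path = path.parent / sp_path
            out.append((float(row["concentration_M"]),
                        read_spectrum(sp_path, units=units)))
    return out
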