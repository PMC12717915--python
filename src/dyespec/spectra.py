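"""Spectral data model and shared lineshape operations.

The central container is :class:`Spectrum`: absorbance (or any linear
response) sampled on a strictly increasing photon-energy grid in eV.
Discrete vibronic lines live in :class:`StickSpectrum` until they are
broadened into a :class:`Spectrum` by :func:`convolve_gaussian`.

Sign convention for :func:`apply_energy_offset`: a positive offset shifts
every feature to LOWER energy (a red shift), which is the usual direction of
the correction applied to overestimated computed excitation energies.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .constants import HC_EV_NM

log = logging.getLogger(__name__)

PROVENANCES = ("computed", "measured", "synthetic")


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrum:
    """A sampled lineshape on a strictly increasing energy grid.

    Parameters
    ----------
    energies : array of float
        Photon energies in eV, strictly increasing, all finite, length >= 2.
    values : array of float
        Absorbance / molar absorptivity / extinction per grid point
        (arbitrary linear units), all finite, same length as ``energies``.
    label : str
        Free-text description.
    provenance : {"computed", "measured", "synthetic"}
    """

    energies: np.ndarray
    values: np.ndarray
    label: str = ""
    provenance: str = "computed"

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "values", v)
        if e.ndim != 1 or v.ndim != 1 or e.size != v.size:
            raise ValueError("energies and values must be 1-D arrays of equal length")
        if e.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(e)) or not np.all(np.isfinite(v)):
            raise ValueError("spectrum contains non-finite entries")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")

    def with_values(self, values: np.ndarray, label: str | None = None) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float),
                       label=self.label if label is None else label)

    @property
    def spacing(self) -> float:
        """Median grid spacing in eV."""
        return float(np.median(np.diff(self.energies)))

    def area(self) -> float:
        """Trapezoid integral of values over the energy grid."""
        return float(np.trapezoid(self.values, self.energies))


@dataclass(frozen=True)
class StickLine:
    """One vibronic transition: position, intensity and its quantum-number
    assignment as a tuple of (mode_index, initial_quanta, final_quanta)."""

    energy: float
    intensity: float
    assignment: tuple[tuple[int, int, int], ...] = ()

    def assignment_string(self) -> str:
        return "|".join(f"{j}:{m}-{n}" for j, m, n in self.assignment)


@dataclass(frozen=True)
class StickSpectrum:
    """Discrete vibronic lines prior to broadening."""

    lines: tuple[StickLine, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "lines", tuple(self.lines))
        if any(l.intensity < 0 for l in self.lines):
            raise ValueError("stick intensities must be non-negative")

    @property
    def energies(self) -> np.ndarray:
        return np.array([l.energy for l in self.lines], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([l.intensity for l in self.lines], dtype=float)

    def total_intensity(self) -> float:
        return float(self.intensities.sum()) if self.lines else 0.0

    def strongest(self) -> StickLine:
        if not self.lines:
            raise ValueError("empty stick spectrum")
        return max(self.lines, key=lambda l: l.intensity)


@dataclass(frozen=True)
class Peak:
    energy_ev: float
    height: float
    score: float


@dataclass(frozen=True)
class Shoulder:
    energy_ev: float
    score: float


@dataclass(frozen=True)
class PeakSet:
    """Local maxima and inflection shoulders found in a spectrum, each with a
    detection score (dimensionless curvature for shoulders, prominence-like
    height for peaks). Peaks are sorted ascending in energy."""

    peaks: tuple[Peak, ...] = ()
    shoulders: tuple[Shoulder, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks",
                           tuple(sorted(self.peaks, key=lambda p: p.energy_ev)))
        object.__setattr__(self, "shoulders",
                           tuple(sorted(self.shoulders, key=lambda s: s.energy_ev)))

    def to_json(self) -> str:
        return json.dumps({
            "peaks": [{"energy_ev": p.energy_ev, "height": p.height,
                       "score": p.score} for p in self.peaks],
            "shoulders": [{"energy_ev": s.energy_ev, "score": s.score}
                          for s in self.shoulders],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PeakSet":
        d = json.loads(text)
        return cls(
            peaks=tuple(Peak(p["energy_ev"], p["height"], p.get("score", 0.0))
                        for p in d.get("peaks", [])),
            shoulders=tuple(Shoulder(s["energy_ev"], s.get("score", 0.0))
                            for s in d.get("shoulders", [])),
        )


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def nm_to_ev(wavelength_nm: float) -> float:
    """Photon energy in eV for a vacuum wavelength in nm (E = hc / lambda)."""
    if np.any(np.asarray(wavelength_nm) <= 0):
        raise ValueError("wavelength must be positive")
    return HC_EV_NM / wavelength_nm


def ev_to_nm(energy_ev: float) -> float:
    """Vacuum wavelength in nm for a photon energy in eV."""
    if np.any(np.asarray(energy_ev) <= 0):
        raise ValueError("energy must be positive")
    return HC_EV_NM / energy_ev


def energy_shift_mev(lambda1_nm: float, lambda2_nm: float) -> float:
    """Energy shift in meV going from lambda1 to lambda2.

    Positive when lambda2 < lambda1, i.e. a blue shift.
    """
    return (nm_to_ev(lambda2_nm) - nm_to_ev(lambda1_nm)) * 1000.0


# ---------------------------------------------------------------------------
# lineshape operations
# ---------------------------------------------------------------------------

def make_grid(e_min: float, e_max: float, spacing: float) -> np.ndarray:
    """Uniform energy grid [e_min, e_max] with at most ``spacing`` step."""
    n = max(2, int(math.ceil((e_max - e_min) / spacing)) + 1)
    return np.linspace(e_min, e_max, n)


def convolve_gaussian(sticks: StickSpectrum, width: float,
                      grid: np.ndarray, *, width_kind: str = "sigma",
                      label: str = "", provenance: str = "computed") -> Spectrum:
    """Broaden a stick spectrum with unit-area Gaussians.

    Each line becomes a normalized Gaussian scaled by its intensity, so the
    integrated area of the result equals the total stick intensity (to within
    grid-discretization error; <0.1% when the grid spacing is <= width/5 and
    covers every stick +- 5 widths).

    Parameters
    ----------
    width : float
        Gaussian width in eV. Interpreted as the standard deviation by
        default; pass ``width_kind="fwhm"`` for a full width at half maximum.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if width_kind == "sigma":
        sigma = width
    elif width_kind == "fwhm":
        sigma = width / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    else:
        raise ValueError("width_kind must be 'sigma' or 'fwhm'")

    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    if not sticks.lines:
        return Spectrum(grid, out, label=label, provenance=provenance)

    e = sticks.energies
    if grid[0] > e.min() - 5 * sigma or grid[-1] < e.max() + 5 * sigma:
        log.warning("grid [%.4f, %.4f] eV does not cover sticks +- 5 widths",
                    grid[0], grid[-1])
    if np.median(np.diff(grid)) > sigma / 5:
        log.warning("grid spacing %.2g eV is coarse relative to width %.2g eV",
                    float(np.median(np.diff(grid))), sigma)

    norm = 1.0 / (sigma * math.sqrt(2.0 * math.pi))
    # outer difference: (n_grid, n_lines)
    z = (grid[:, None] - e[None, :]) / sigma
    out = norm * np.exp(-0.5 * z * z) @ sticks.intensities
    return Spectrum(grid, out, label=label, provenance=provenance)


def baseline_correct(spectrum: Spectrum) -> Spectrum:
    """Subtract the minimum value so the lowest point sits at zero.

    Shape-preserving (all pairwise differences unchanged) and idempotent.
    """
    return spectrum.with_values(spectrum.values - spectrum.values.min())


def apply_energy_offset(obj: "Spectrum | StickSpectrum", offset: float):
    """Rigidly shift a spectrum or stick spectrum by ``-offset`` eV.

    A positive offset is a red shift: every energy moves DOWN by ``offset``.
    Returns the same type as the input.
    """
    if not math.isfinite(offset):
        raise ValueError("offset must be finite")
    if isinstance(obj, StickSpectrum):
        return StickSpectrum(tuple(
            StickLine(l.energy - offset, l.intensity, l.assignment)
            for l in obj.lines))
    if isinstance(obj, Spectrum):
        return replace(obj, energies=obj.energies - offset)
    raise TypeError(f"cannot shift object of type {type(obj).__name__}")


def resample(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation onto a new grid inside the source range.

    Extrapolation is an error, never a fill. Values at grid points shared
    with the source are copied exactly.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] < spectrum.energies[0] - 1e-12 or grid[-1] > spectrum.energies[-1] + 1e-12:
        raise ValueError(
            f"target grid [{grid[0]:.6g}, {grid[-1]:.6g}] extends beyond source "
            f"range [{spectrum.energies[0]:.6g}, {spectrum.energies[-1]:.6g}]")
    vals = np.interp(grid, spectrum.energies, spectrum.values)
    # copy exactly at shared points (interp can round in the last ulp)
    idx = np.searchsorted(spectrum.energies, grid)
    idx = np.clip(idx, 0, spectrum.energies.size - 1)
    exact = spectrum.energies[idx] == grid
    vals[exact] = spectrum.values[idx[exact]]
    return Spectrum(grid, vals, label=spectrum.label, provenance=spectrum.provenance)


# ---------------------------------------------------------------------------
# peak and shoulder detection
# ---------------------------------------------------------------------------

def detect_peaks(spectrum: Spectrum, smoothing: float = 0.01,
                 shoulder_threshold: float = 0.02) -> PeakSet:
    """Locate peaks and shoulders of a sampled lineshape.

    The curve is smoothed with a local-polynomial (Savitzky-Golay) filter of
    window ~5x the ``smoothing`` parameter. Peaks are strict local maxima of
    the smoothed curve. Shoulder candidates are local minima of the smoothed
    second derivative (negative-curvature lobes, i.e. buried bands) that do
    not coincide with a detected peak; they are kept when their dimensionless
    curvature score ``-y'' * smoothing^2 / max|y|`` exceeds
    ``shoulder_threshold``.

    Parameters
    ----------
    smoothing : float
        Smoothing length scale in eV; the spectrum must be sampled at least
        3 points per ``smoothing``.
    shoulder_threshold : float
        Minimum dimensionless curvature score for a shoulder.
    """
    e, y = spectrum.energies, spectrum.values
    dx = spectrum.spacing
    if dx > smoothing / 3:
        raise ValueError(
            f"grid spacing {dx:.3g} eV too coarse for smoothing {smoothing:.3g} eV "
            "(need spacing <= smoothing/3)")
    window = int(round(5 * smoothing / dx))
    window = max(5, window | 1)  # odd, >= 5
    if window >= e.size:
        raise ValueError("spectrum shorter than the smoothing window")

    ys = savgol_filter(y, window, 3)
    d2 = savgol_filter(y, window, 3, deriv=2, delta=dx)
    scale = float(np.max(np.abs(ys)))
    if scale == 0.0:
        return PeakSet()

    # the prominence and height floors suppress local-polynomial smoothing
    # artifacts (flank ringing reaches ~1e-3 of the maximum when the window
    # is wider than a band), not physical features
    floor = 1e-4 * scale
    pk_idx, _ = find_peaks(ys, prominence=floor, height=1e-3 * scale)
    peaks = tuple(Peak(float(e[i]), float(ys[i]),
                       float(-d2[i] * smoothing ** 2 / scale)) for i in pk_idx)

    # negative-curvature lobes: local minima of the second derivative
    cand_idx, _ = find_peaks(-d2)
    guard = max(window // 2, 1)
    shoulders = []
    for i in cand_idx:
        if d2[i] >= 0:
            continue
        if i < guard or i > e.size - 1 - guard:
            continue  # boundary artifacts of the filter
        if pk_idx.size and np.min(np.abs(e[pk_idx] - e[i])) < smoothing:
            continue  # this lobe belongs to a resolved peak
        score = float(-d2[i] * smoothing ** 2 / scale)
        if score >= shoulder_threshold:
            shoulders.append(Shoulder(float(e[i]), score))
    return PeakSet(peaks=peaks, shoulders=tuple(shoulders))
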