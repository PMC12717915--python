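"""End-to-end pipeline: vibronic spectrum -> equilibrium mixing -> peak
analysis -> cavity coupling.

``run_pipeline`` executes the four stages in order, writes every
intermediate artifact under the configured output directory and finishes
with a manifest (inputs, seed, config hash, per-file SHA-256 checksums).
Re-running an identical config reproduces identical bytes; a stage failure
aborts with the stage name and leaves a FAILED marker next to the partial
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as dio
from .dimer import DimerizationModel, composite_spectrum
from .franck_condon import thermal_stick_spectrum
from .polariton import analyze_polaritons, extinction_spectrum
from .spectra import (Spectrum, apply_energy_offset, convolve_gaussian,
                      detect_peaks, make_grid, resample)
from .synthetic import (ARBITRARY_DEFAULTS, GeneratorConfig,
                        make_cavity_fixture, make_dimer_bands,
                        make_meb_monomer)

log = logging.getLogger(__name__)

STAGES = ("fcspec", "mix", "peaks", "cavity")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything `run_pipeline` needs; round-trips through YAML unchanged."""

    outdir: str = "dyespec_run"
    seed: int = 0
    width_ev: float = 0.022
    width_kind: str = "sigma"
    offset_ev: float = 0.0
    grid_min: float = 1.70
    grid_max: float = 2.60
    grid_spacing: float = 0.002
    k_d: float = ARBITRARY_DEFAULTS["k_d"]
    c_i: float = 5.0e-4
    eps_m: float = ARBITRARY_DEFAULTS["eps_m"]
    eps_d: float = ARBITRARY_DEFAULTS["eps_d"]
    vibronic_path: str | None = None   # YAML/JSON; default: synthetic monomer
    cavity_path: str | None = None     # YAML/JSON; default: two-line fixture
    cavity_mode: str = "extinction"
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage(s) {bad}; expected {STAGES}")
        object.__setattr__(self, "stages", tuple(self.stages))

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def to_yaml(self, path: "str | Path") -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def grid(self) -> np.ndarray:
        return make_grid(self.grid_min, self.grid_max, self.grid_spacing)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.config_hash(),
                      "seed": config.seed, "stages": [], "artifacts": {}}
    grid = config.grid()
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    state: dict = {}

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path),
                                       "sha256": _sha256(path)}

    def stage_fcspec() -> None:
        if config.vibronic_path:
            system = dio.load_vibronic_system(config.vibronic_path)
            manifest["inputs"] = {"vibronic": config.vibronic_path}
        else:
            system = make_meb_monomer()
        sticks = thermal_stick_spectrum(system)
        if config.offset_ev:
            sticks = apply_energy_offset(sticks, config.offset_ev)
        spec = convolve_gaussian(sticks, config.width_ev, grid,
                                 width_kind=config.width_kind,
                                 label="monomer vibronic spectrum")
        area = spec.area()
        if area > 0:
            spec = spec.with_values(spec.values / area)
        state["monomer"] = spec
        p1, p2 = outdir / "monomer_sticks.csv", outdir / "monomer_spectrum.csv"
        dio.write_sticks(sticks, p1)
        dio.write_spectrum(spec, p2)
        record("monomer_sticks", p1)
        record("monomer_spectrum", p2)

    def stage_mix() -> None:
        a_m = state.get("monomer")
        if a_m is None:
            a_m = dio.read_spectrum(outdir / "monomer_spectrum.csv",
                                    units="ev")
        a_da = make_dimer_bands("parallel", grid=grid)
        a_db = make_dimer_bands("antiparallel", grid=grid)
        if config.offset_ev:
            a_da = apply_energy_offset(a_da, config.offset_ev)
            a_db = apply_energy_offset(a_db, config.offset_ev)
            a_da = resample(a_da, grid[(grid >= a_da.energies[0]) &
                                       (grid <= a_da.energies[-1])])
            a_db = resample(a_db, a_da.energies)
            a_m = resample(a_m, a_da.energies)
        model = DimerizationModel(k_d=config.k_d, c_i=config.c_i,
                                  eps_m=config.eps_m, eps_d=config.eps_d)
        total = composite_spectrum(model, a_m, a_da, a_db)
        state["mixture"] = total
        p = outdir / "solution_spectrum.csv"
        dio.write_spectrum(total, p)
        record("solution_spectrum", p)

    def stage_peaks() -> None:
        spec = state.get("mixture") or state.get("monomer")
        if spec is None:
            spec = dio.read_spectrum(outdir / "solution_spectrum.csv",
                                     units="ev")
        ps = detect_peaks(spec)
        p = outdir / "peaks.json"
        p.write_text(ps.to_json() + "\n")
        record("peaks", p)

    def stage_cavity() -> None:
        if config.cavity_path:
            model = dio.load_cavity_model(config.cavity_path)
        else:
            model = make_cavity_fixture(include_vibronic=True)
        span = max([model.kappa] + [t.gamma for t in model.transitions])
        centers = [model.omega_c] + [t.omega for t in model.transitions]
        gmin = min(centers) - 5 * span - 2 * sum(t.g for t in model.transitions)
        gmax = max(centers) + 5 * span + 2 * sum(t.g for t in model.transitions)
        cav_grid = make_grid(gmin, gmax, 0.0005)
        ext = extinction_spectrum(model, cav_grid, mode=config.cavity_mode)
        p = outdir / "cavity_extinction.csv"
        dio.write_spectrum(ext, p)
        record("cavity_extinction", p)
        try:
            rep = analyze_polaritons(ext)
            report = dataclasses.asdict(rep)
        except ValueError as exc:
            report = {"error": str(exc)}
        pr = outdir / "polariton_report.json"
        pr.write_text(json.dumps(report, indent=2) + "\n")
        record("polariton_report", pr)

    runners = {"fcspec": stage_fcspec, "mix": stage_mix,
               "peaks": stage_peaks, "cavity": stage_cavity}
    for name in config.stages:
        t0 = time.perf_counter()
        try:
            runners[name]()
        except Exception as exc:
            failed_marker.write_text(f"stage {name} failed: {exc}\n")
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %s completed in %.2f s", name,
                 time.perf_counter() - t0)
        manifest["stages"].append(name)

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
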