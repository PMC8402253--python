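"""Configuration, orchestration and reproducibility plumbing.

`WorkbenchConfig` validates every parameter against the module preconditions
before any compute starts; `run_command` dispatches to the library and writes
each output next to an atomically-written JSON run manifest (config echo,
model hash, seed, ledger totals, wall time, output checksums), so any output
can be regenerated bit-identically from its manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigValidationError, UnknownPresetError
from .mc_engine import DetectorAnnuli, RunConfig, run_simulation
from .oximetry import (
    ExtinctionTable,
    ProbeGeometry,
    build_slope_lut,
    process_reading_log,
    STANDARD_PROBES,
)
from .phantom import PhantomSpec, phantom_depth_sweep
from .sensitivity import (
    dp_regression_protocol,
    fine_annuli_for,
    maps_to_frame,
    pair_depth_profile,
    profile_metrics,
)
from .tissue_models import PRESET_NAMES, TissueModel, make_preset_model


@dataclass
class WorkbenchConfig:
    """Validated parameters shared by the workbench commands."""

    model: str = "homogeneous_skin"  # preset name or path to a YAML model
    wavelength: int = 770
    photons: int = 200_000
    seed: int = 1
    voxel_size: float = 0.2
    tally_mode: str = "depth_profile"
    ring_width: float = 1.0
    ring_step: float = 0.5
    r_max: float = 31.0
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    probes: tuple = STANDARD_PROBES
    rho2_list: tuple = (5.0, 10.0, 20.0, 30.0)
    inversion: str = "lut"
    extinction_path: str | None = None
    mu_a_grid: tuple = (0.001, 0.06, 25)  # lo, hi, n
    depths: tuple = (0.5, 10.0, 0.5)  # lo, hi, step (top-of-blood-layer)
    out_dir: str = "srsoxi_out"

    _KNOWN = None  # populated below

    def __post_init__(self):
        if self.photons < 1:
            raise ConfigValidationError("photons must be >= 1")
        if not self.voxel_size > 0:
            raise ConfigValidationError("voxel_size must be > 0")
        if not self.ring_width > 0:
            raise ConfigValidationError("ring_width must be > 0")
        if self.tally_mode not in ("depth_profile", "full_3d"):
            raise ConfigValidationError(f"unknown tally_mode {self.tally_mode!r}")
        if self.inversion not in ("lut", "diffusion"):
            raise ConfigValidationError(f"unknown inversion {self.inversion!r}")
        if self.wavelength not in (770, 830):
            raise ConfigValidationError(f"unknown wavelength {self.wavelength}")
        for rho1, rho2 in self.probes:
            if not 0 < rho1 < rho2:
                raise ConfigValidationError(f"bad probe ({rho1}, {rho2})")

    def run_config(self, **overrides) -> RunConfig:
        base = dict(
            n_photons=self.photons,
            seed=self.seed,
            voxel_size=self.voxel_size,
            tally_mode=self.tally_mode,
            roulette_threshold=self.roulette_threshold,
            roulette_survival=self.roulette_survival,
        )
        base.update(overrides)
        return RunConfig(**base)

    def tissue_model(self) -> TissueModel:
        if self.model in PRESET_NAMES:
            return make_preset_model(self.model, self.wavelength)
        path = Path(self.model)
        if not path.exists():
            raise UnknownPresetError(
                f"model {self.model!r} is neither a preset {PRESET_NAMES} "
                "nor an existing file"
            )
        return TissueModel.from_yaml(path)

    def extinction(self) -> ExtinctionTable:
        return ExtinctionTable.from_csv(self.extinction_path)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("_KNOWN", None)
        d["probes"] = [list(p) for p in self.probes]
        d["rho2_list"] = list(self.rho2_list)
        d["mu_a_grid"] = list(self.mu_a_grid)
        d["depths"] = list(self.depths)
        return d


WorkbenchConfig._KNOWN = frozenset(
    f.name for f in dataclasses.fields(WorkbenchConfig) if f.name != "_KNOWN"
)


def load_config(path=None, **overrides) -> WorkbenchConfig:
    """Load a YAML/JSON config file, apply overrides, validate everything.

    Unknown keys are rejected by name.
    """
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigValidationError("config file must contain a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(data) - WorkbenchConfig._KNOWN
    if unknown:
        raise ConfigValidationError(
            f"unknown config keys: {sorted(unknown)}; "
            f"known keys: {sorted(WorkbenchConfig._KNOWN)}"
        )
    for key in ("probes", "rho2_list", "mu_a_grid", "depths"):
        if key in data and data[key] is not None:
            data[key] = tuple(
                tuple(v) if isinstance(v, (list, tuple)) else v for v in data[key]
            )
    return WorkbenchConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out_dir: Path, command: str, cfg: WorkbenchConfig,
                    model: TissueModel | None, outputs, extra=None,
                    t0: float = 0.0) -> Path:
    manifest = {
        "tool_version": __version__,
        "command": command,
        "config": cfg.to_dict(),
        "model_hash": model.content_hash() if model is not None else None,
        "seed": cfg.seed,
        "wall_time_s": round(time.perf_counter() - t0, 3),
        "outputs": {str(p.name): _sha256(p) for p in outputs},
    }
    if extra:
        manifest.update(extra)
    path = out_dir / f"{command}_manifest.json"
    tmp = path.with_suffix(".json.tmp")
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    os.replace(tmp, path)
    return path


def run_command(command: str, cfg: WorkbenchConfig) -> dict:
    """Dispatch one workbench command; returns {'outputs': [...], 'manifest': ...}."""
    t0 = time.perf_counter()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = []
    extra = {}
    model = None

    if command == "simulate":
        model = cfg.tissue_model()
        annuli = DetectorAnnuli.uniform(cfg.ring_step, cfg.r_max)
        tallies = run_simulation(model, cfg.run_config(), annuli)
        path = out_dir / "tallies.h5"
        tallies.to_hdf5(path)
        outputs.append(path)
        extra["ledger"] = {
            "launched": tallies.launched,
            "detected": tallies.detected_weight,
            "absorbed": tallies.absorbed_weight,
            "transmitted": tallies.transmitted_weight,
            "escaped": tallies.escaped_outside_weight,
            "closure": tallies.ledger_closure,
        }

    elif command in ("sensitivity", "metrics"):
        model = cfg.tissue_model()
        annuli = fine_annuli_for(max(p[1] for p in cfg.probes), cfg.ring_step)
        tallies = run_simulation(model, cfg.run_config(), annuli)
        rows = []
        for rho1, rho2 in cfg.probes:
            prof = pair_depth_profile(tallies, rho1, rho2, cfg.ring_width)
            m = profile_metrics(prof)
            rows.append(
                {
                    "pair": f"{rho1:g}-{rho2:g} mm",
                    "peak_depth_mm": m.peak_depth,
                    "half_range_low_mm": m.half_range_low,
                    "half_range_high_mm": m.half_range_high,
                    "depth_10pct_mm": m.depth_10pct,
                }
            )
            prof_path = out_dir / f"profile_{rho1:g}_{rho2:g}.csv"
            prof.to_frame().to_csv(prof_path, index=False)
            outputs.append(prof_path)
        path = out_dir / "profile_metrics.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        outputs.append(path)

    elif command == "map":
        model = cfg.tissue_model()
        annuli = fine_annuli_for(max(cfg.rho2_list), cfg.ring_step)
        tallies = run_simulation(
            model, cfg.run_config(voxel_size=cfg.voxel_size), annuli
        )
        maps = [
            sweep_depth_map(model, rho2, cfg.run_config(), tallies=tallies,
                            ring_width=cfg.ring_width)
            for rho2 in cfg.rho2_list
        ]
        path = out_dir / "depth_map_points.csv"
        maps_to_frame(maps).to_csv(path, index=False)
        outputs.append(path)
        reg = fit_dp_regression(maps)
        extra["regression"] = dataclasses.asdict(reg)
        rpath = out_dir / "dp_regression.json"
        rpath.write_text(json.dumps(dataclasses.asdict(reg), indent=2))
        outputs.append(rpath)

    elif command == "regress":
        frame = pd.read_csv(out_dir / "depth_map_points.csv")
        X = np.column_stack(
            [frame["rho1_mm"], frame["rho2_mm"], np.ones(len(frame))]
        )
        beta, *_ = np.linalg.lstsq(X, frame["peak_depth_mm"], rcond=None)
        reg = {
            "coef_rho1": float(beta[0]),
            "coef_rho2": float(beta[1]),
            "intercept": float(beta[2]),
            "n_points": int(len(frame)),
        }
        path = out_dir / "dp_regression.json"
        path.write_text(json.dumps(reg, indent=2))
        outputs.append(path)
        extra["regression"] = reg

    elif command == "lut":
        model = cfg.tissue_model()
        lo, hi, n = cfg.mu_a_grid
        grid = np.linspace(float(lo), float(hi), int(n))
        for rho1, rho2 in cfg.probes:
            probe = ProbeGeometry(rho1, rho2)
            lut = build_slope_lut(
                model.props(0), probe, grid, cfg.run_config(),
                wavelength=cfg.wavelength,
            )
            path = out_dir / f"lut_{rho1:g}_{rho2:g}_{cfg.wavelength}.csv"
            with open(path, "w") as fh:
                fh.write(
                    f"# probe {rho1:g}/{rho2:g} mm, {cfg.wavelength} nm, "
                    f"mu_s={lut.mu_s} g={lut.g} n={lut.n} "
                    f"config_hash={lut.config_hash}\n"
                )
                lut.to_frame().to_csv(fh, index=False)
            outputs.append(path)

    elif command == "phantom":
        spec = PhantomSpec()
        lo, hi, step = cfg.depths
        depths = np.arange(float(lo), float(hi) + 1e-9, float(step))
        sweep = phantom_depth_sweep(
            spec, cfg.probes, depths,
            cfg.run_config(voxel_size=0.5),
            cfg.extinction(), inversion=cfg.inversion,
        )
        path = out_dir / "phantom_sweep.csv"
        sweep.to_csv(path, index=False)
        outputs.append(path)

    elif command == "oximeter":
        frame = pd.read_csv(out_dir / "readings.csv")
        probe = ProbeGeometry(*cfg.probes[0])
        result = process_reading_log(
            frame, probe, cfg.extinction(), inversion="diffusion",
            mu_s_prime=1.2,
        )
        path = out_dir / "oximeter_output.csv"
        result.to_csv(path, index=False)
        outputs.append(path)

    else:
        raise ConfigValidationError(f"unknown command {command!r}")

    manifest = _write_manifest(out_dir, command, cfg, model, outputs, extra, t0)
    return {"outputs": [str(p) for p in outputs], "manifest": str(manifest),
            **extra}
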