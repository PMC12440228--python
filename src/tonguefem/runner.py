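"""Config-driven entry points with reproducible run manifests.

This is the programmatic face of the package for scripted use: a validated
:class:`RunConfig` (optionally loaded from YAML) selects one of the
standard computations — phantom generation, a phoneme posture, a transient
simulation, a convergence study or a mesh quality report — and ``run``
executes it, writing outputs plus a manifest (config echo, config hash,
seed, package versions) to the output directory.  A dry run resolves and
reports everything (e.g. activation schedules) without touching the solver.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .convergence import run_convergence
from .mesh_io import write_mesh, write_vtu
from .muscles import PHONEMES
from .phantom import PhantomSpec, generate_tongue_phantom
from .quality import quality_report
from .solver import apply_phoneme_preset, solve_phoneme_posture

_COMMANDS = ("phantom", "phoneme", "converge", "quality")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Schema-validated run configuration.  Unknown keys are rejected."""
    command: str = "phantom"
    output_dir: str = "runs/out"
    seed: int = 0
    phantom: dict = field(default_factory=dict)      # PhantomSpec overrides
    phoneme: str | None = None                       # for command="phoneme"
    load_scale_steps: int = 3
    n_levels: int = 3                                # for command="converge"
    threshold_mm: float = 1.0
    half_model: bool = True
    dry_run: bool = False

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self):
        if self.command not in _COMMANDS:
            raise ConfigError(f"unknown command {self.command!r}; "
                              f"known: {_COMMANDS}")
        if self.command == "phoneme":
            if self.phoneme not in PHONEMES:
                raise ConfigError(f"unknown phoneme {self.phoneme!r}; "
                                  f"known: {set(PHONEMES)}")
        spec_fields = {f.name for f in dataclasses.fields(PhantomSpec)}
        unknown = set(self.phantom) - spec_fields
        if unknown:
            raise ConfigError(f"unknown phantom keys: {sorted(unknown)}")

    def phantom_spec(self) -> PhantomSpec:
        kw = dict(self.phantom)
        kw.setdefault("seed", self.seed)
        if self.command == "phoneme":
            kw.setdefault("symmetric_half", self.half_model)
        return PhantomSpec(**kw)

    def digest(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def run(config: RunConfig | dict) -> dict:
    """Execute a configured run; returns the finalized manifest."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": dataclasses.asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        "versions": {"tonguefem": __version__, "numpy": np.__version__},
        "status": "running",
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))

    try:
        result = _dispatch(config, out)
        manifest.update(result, status="completed")
    except Exception as err:
        manifest.update(status="failed", error=str(err))
        manifest_path.write_text(json.dumps(manifest, indent=1))
        raise
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


def _dispatch(config: RunConfig, out: Path) -> dict:
    if config.command == "phantom":
        mesh = generate_tongue_phantom(config.phantom_spec())
        write_mesh(mesh, out / "phantom.json", "internal-container")
        write_vtu(mesh, out / "phantom.vtu")
        return {"n_nodes": mesh.n_nodes, "n_elements": mesh.n_elements}

    if config.command == "quality":
        mesh = generate_tongue_phantom(config.phantom_spec())
        rep = quality_report(mesh)
        (out / "quality.json").write_text(json.dumps(rep.summary(), indent=1))
        return {"quality": rep.summary()}

    if config.command == "phoneme":
        schedules, _bc = apply_phoneme_preset(config.phoneme)
        resolved = {s.muscle: s.plateau for s in schedules}
        if config.dry_run:
            return {"phoneme": config.phoneme, "dry_run": True,
                    "schedules_pa": resolved}
        mesh, res = solve_phoneme_posture(
            config.phoneme, spec=config.phantom_spec(),
            half=config.half_model,
            load_scale_steps=config.load_scale_steps)
        write_vtu(mesh, out / f"phoneme_{config.phoneme}.vtu",
                  point_data={"displacement_mm": res.final_displacement})
        landmarks = {k: v[-1].tolist()
                     for k, v in res.landmark_trajectories.items()}
        (out / "landmarks.json").write_text(json.dumps(landmarks, indent=1))
        return {"phoneme": config.phoneme, "schedules_pa": resolved,
                "landmarks_mm": landmarks,
                "J_range": [float(res.element_J[-1].min()),
                            float(res.element_J[-1].max())]}

    if config.command == "converge":
        rep = run_convergence(config.phantom_spec(),
                              n_levels=config.n_levels,
                              threshold_mm=config.threshold_mm)
        rep.save(out / "convergence.json")
        (out / "convergence.csv").write_text(rep.to_csv())
        return {"node_counts": [int(n) for n in rep.node_counts],
                "selected_level": rep.selected_level}

    raise ConfigError(f"unhandled command {config.command}")
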