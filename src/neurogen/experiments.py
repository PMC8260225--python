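"""Reproducible experiment runner: configs, manifests, result files.

An experiment is described by a YAML config with sections
``{experiment, dataset, network, plasticity, simple, plan, seeds, out}``.
``run_experiment`` validates the config, dispatches to the protocol or
simplified-network plans, and writes

* an HDF5 bundle (weights, trajectories),
* a CSV of scalar metrics per phase,
* a JSON manifest (config snapshot, seeds, package version, SHA-256
  checksums of every weight matrix) — reruns of an identical manifest
  reproduce identical checksums.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .datasets import ClusterSpec, PatternSet, build_dataset
from .network import NetworkConfig
from .plasticity import PlasticityConfig
from .protocols import ExperimentPlan, run_neurogenesis
from .simple import SimpleNetConfig, run_simple_neurogenesis

__all__ = ["RunManifest", "ExperimentConfigError", "load_config",
           "run_experiment", "make_fixtures"]

_EXPERIMENTS = ("toy", "neurogenesis", "control", "pretrain")


class ExperimentConfigError(ValueError):
    """A config failed schema validation; message names the field."""


@dataclass
class RunManifest:
    """Provenance record written next to every result bundle."""

    experiment: str
    config: dict
    seeds: dict
    version: str = __version__
    checksums: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def add_array(self, name: str, arr: np.ndarray) -> None:
        self.checksums[name] = hashlib.sha256(
            np.ascontiguousarray(arr).tobytes()).hexdigest()

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2,
                                         default=str))


def _require(cfg: dict, section: str, cls, defaults=None):
    """Build a config dataclass from a YAML section with field checking."""
    params = dict(defaults or {})
    params.update(cfg.get(section) or {})
    valid = set(cls.__dataclass_fields__)
    unknown = set(params) - valid
    if unknown:
        raise ExperimentConfigError(
            f"section '{section}': unknown field(s) {sorted(unknown)}; "
            f"valid fields are {sorted(valid)}")
    try:
        return cls(**params)
    except (TypeError, ValueError) as exc:
        raise ExperimentConfigError(f"section '{section}': {exc}") from exc


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ExperimentConfigError("config must be a YAML mapping")
    name = cfg.get("experiment")
    if name not in _EXPERIMENTS:
        raise ExperimentConfigError(
            f"field 'experiment': got {name!r}, expected one of "
            f"{_EXPERIMENTS}")
    return cfg


def run_experiment(config_path, out_dir, seed: int | None = None,
                   ) -> RunManifest:
    """Run the experiment described by a YAML config; write result bundle."""
    import h5py

    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(cfg.get("seeds") or {})
    if seed is not None:
        seeds["base"] = seed
    seeds.setdefault("base", 0)

    spec = _require(cfg, "dataset", ClusterSpec,
                    defaults={"K": 7, "xi": 0.2, "seed": seeds["base"]})
    manifest = RunManifest(cfg["experiment"], cfg, seeds)
    metrics: list[tuple[str, float]] = []

    h5_path = out / "results.h5"
    with h5py.File(h5_path, "w") as f:
        if cfg["experiment"] == "toy":
            scfg = _require(cfg, "simple", SimpleNetConfig)
            train, _ = build_dataset(spec)
            traj = run_simple_neurogenesis(train, scfg, seed=seeds["base"])
            f.create_dataset("norms", data=traj.norms)
            f.create_dataset("phis", data=traj.phis)
            f.create_dataset("W", data=traj.W)
            f.attrs["phase_split"] = traj.phase_split
            f.attrs["case"] = traj.case
            manifest.add_array("W", traj.W)
            metrics += [("end_of_early_norm", traj.end_of_early_norm),
                        ("end_of_early_phi_deg", traj.end_of_early_phi),
                        ("final_norm", traj.final_norm),
                        ("final_phi_deg", traj.final_phi)]
        else:
            ncfg = _require(cfg, "network", NetworkConfig,
                            defaults={"n_ec": spec.n_ec})
            pcfg = _require(cfg, "plasticity", PlasticityConfig)
            plan = _require(cfg, "plan", ExperimentPlan,
                            defaults={"seed": seeds["base"]})
            if cfg["experiment"] == "control" and plan.control is None:
                raise ExperimentConfigError(
                    "section 'plan': control experiments need a "
                    "'control' variant")
            train, _ = build_dataset(spec)
            result = run_neurogenesis(plan, train, ncfg, pcfg)
            f.create_dataset("W", data=result.state.W)
            f.create_dataset("b", data=result.state.b)
            f.create_dataset("selective", data=result.selective)
            f.create_dataset("unresponsive", data=result.unresponsive)
            f.create_dataset("newborn", data=result.newborn)
            for phase, W in result.snapshots.items():
                f.create_dataset(f"snapshots/{phase}", data=W)
                manifest.add_array(f"W_{phase}", W)
            for phase, norms in result.newborn_norms.items():
                f.create_dataset(f"newborn_norms/{phase}", data=norms)
                if norms.size:
                    metrics.append((f"newborn_norm_end_{phase}",
                                    float(norms[-1])))
            manifest.add_array("W", result.state.W)
            metrics += [("n_selective", float(result.selective.size)),
                        ("n_unresponsive", float(result.unresponsive.size))]

    csv_path = out / "metrics.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["metric", "value"])
        writer.writerows(metrics)

    manifest.outputs = [str(h5_path), str(csv_path)]
    manifest.write(out / "manifest.json")
    return manifest


def make_fixtures(seed: int = 0) -> dict[str, PatternSet]:
    """Tiny deterministic pattern sets for fast unit tests.

    K=3 clusters in 8 dimensions, 50 train / 20 test patterns per cluster at
    a moderate concentration, regenerated from the seed at call time.
    """
    spec = ClusterSpec(K=3, xi=0.2, kappa=100.0, n_train=50, n_test=20,
                       seed=seed)
    train, test = build_dataset(spec)
    return {"train": train, "test": test, "spec": spec}
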