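"""Run configuration, persistence, and manifests.

Configs are plain YAML with four blocks (``network``, ``drift``, ``learn``,
``experiment``) plus ``seed`` and ``output_dir``; every key is validated and
unknown keys are rejected by name.  An empty file yields the standard
defaults (Nx=15, Ny=12, Nz=1, P=8, α=5, lr=0.001).

Runs persist as: array snapshots in a ``.npz`` container, time series as
CSV, reports as JSON, and finally a ``manifest.json`` recording the resolved
config, consumed seeds, software version, wall-clock metadata, and a sha256
inventory of every written file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .drift import DriftConfig
from .learning import LearnConfig
from .network import NetworkConfig

__all__ = [
    "RunConfig",
    "RunManifest",
    "ConfigError",
    "load_config",
    "dump_config",
    "persist_run",
    "verify_manifest",
    "save_task",
    "load_task",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

_PROTOCOLS = {
    "toy-fig4": {"drift_steps", "sigma"},
    "drift-demo": set(),
    "robustness-sweep": {"umax_grid", "n_seeds", "rho", "n_perturb", "drift_steps"},
    "learnability-sweep": {
        "init_sd_grid",
        "n_seeds",
        "use_allocation",
        "learner",
        "joint_refit",
        "drift_steps",
    },
    "continual": {"n_seeds", "drift_steps", "with_drift", "init_sd", "Umax"},
}


class ConfigError(ValueError):
    """A configuration file failed validation."""


@dataclass(frozen=True)
class RunConfig:
    network: NetworkConfig = field(default_factory=NetworkConfig)
    drift: DriftConfig = field(default_factory=DriftConfig)
    # protocols run at simulation scale, where the adaptive optimizer is the
    # stable choice (plain GD remains the default for the worked example)
    learn: LearnConfig = field(default_factory=lambda: LearnConfig(optimizer="adaptive_gd"))
    experiment: dict = field(default_factory=lambda: {"protocol": "drift-demo"})
    seed: int = 0
    output_dir: str = "runs"


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = _version
    schema_version: int = SCHEMA_VERSION
    created: str = ""
    wall_seconds: float = 0.0
    inventory: dict[str, str] = field(default_factory=dict)  # filename -> sha256


def _build_section(cls, block: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in '{name}' block; allowed: {sorted(allowed)}"
        )
    try:
        return cls(**block)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid '{name}' block: {e}") from e


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration, filling defaults."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {path}: {e}") from e
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    known = {"network", "drift", "learn", "experiment", "seed", "output_dir"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}; allowed: {sorted(known)}")
    net = _build_section(NetworkConfig, raw.get("network", {}) or {}, "network")
    drift_block = dict(raw.get("drift", {}) or {})
    if "constrained" in drift_block and drift_block["constrained"] is not None:
        drift_block["constrained"] = frozenset(drift_block["constrained"])
    drift = _build_section(DriftConfig, drift_block, "drift")
    learn_block = dict(raw.get("learn", {}) or {})
    learn_block.setdefault("optimizer", "adaptive_gd")
    learn = _build_section(LearnConfig, learn_block, "learn")
    exp = dict(raw.get("experiment", {}) or {"protocol": "drift-demo"})
    protocol = exp.get("protocol", "drift-demo")
    if protocol not in _PROTOCOLS:
        raise ConfigError(
            f"unknown protocol {protocol!r}; available: {sorted(_PROTOCOLS)}"
        )
    extra = set(exp) - _PROTOCOLS[protocol] - {"protocol"}
    if extra:
        raise ConfigError(
            f"unknown key(s) {sorted(extra)} for protocol {protocol!r}; "
            f"allowed: {sorted(_PROTOCOLS[protocol])}"
        )
    exp["protocol"] = protocol
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"seed must be an integer, got {seed!r}")
    return RunConfig(
        network=net,
        drift=drift,
        learn=learn,
        experiment=exp,
        seed=seed,
        output_dir=str(raw.get("output_dir", "runs")),
    )


def _section_dict(obj) -> dict:
    d = asdict(obj)
    for k, v in d.items():
        if isinstance(v, frozenset):
            d[k] = sorted(v)
    return d


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a config back to YAML such that load(dump(cfg)) == cfg."""
    doc = {
        "network": _section_dict(cfg.network),
        "drift": _section_dict(cfg.drift),
        "learn": _section_dict(cfg.learn),
        "experiment": dict(cfg.experiment),
        "seed": cfg.seed,
        "output_dir": cfg.output_dir,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _JsonEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def persist_run(
    outputs: dict,
    manifest: RunManifest,
    output_dir: str | Path,
) -> dict[str, str]:
    """Persist run outputs and write the manifest last.

    ``outputs`` maps names to numpy arrays (or dicts of arrays, saved
    together as one ``.npz``), pandas DataFrames (CSV), or JSON-serializable
    reports.  Returns the file inventory (name -> sha256).
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    inventory: dict[str, str] = {}
    for name, obj in outputs.items():
        if isinstance(obj, np.ndarray):
            fname = f"{name}.npz"
            np.savez(out / fname, **{name: obj})
        elif isinstance(obj, dict) and obj and all(
            isinstance(v, np.ndarray) for v in obj.values()
        ):
            fname = f"{name}.npz"
            np.savez(out / fname, **obj)
        elif isinstance(obj, pd.DataFrame):
            fname = f"{name}.csv"
            obj.to_csv(out / fname, index=False)
        else:
            fname = f"{name}.json"
            (out / fname).write_text(
                json.dumps({"schema_version": SCHEMA_VERSION, name: obj}, cls=_JsonEncoder, indent=1)
            )
        inventory[fname] = _sha256(out / fname)
    manifest.inventory = inventory
    manifest.created = manifest.created or time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.wall_seconds += time.time() - t0
    (out / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), cls=_JsonEncoder, indent=1)
    )
    return inventory


def save_task(task, path: str | Path, frame=None) -> None:
    """Serialize a task (and optionally its η frame) as .npz plus a JSON sidecar."""
    path = Path(path)
    arrays = {"X": task.X, "W": task.W, "Z": task.Z}
    if task.T is not None:
        arrays["T"] = task.T
    if frame is not None:
        arrays.update(Xext=frame.Xext, Xinv=frame.Xinv, scales=frame.scales)
    np.savez(path, **arrays)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "seed": task.seed,
        "shapes": {k: list(v.shape) for k, v in arrays.items()},
        "has_frame": frame is not None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_task(path: str | Path):
    """Inverse of :func:`save_task`; returns (TaskSpec, EtaFrame | None)."""
    from .eta import EtaFrame
    from .network import TaskSpec

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        task = TaskSpec(
            X=z["X"], W=z["W"], Z=z["Z"], T=z["T"] if "T" in z else None,
            seed=sidecar.get("seed"),
        )
        frame = None
        if sidecar.get("has_frame"):
            frame = EtaFrame(
                Xext=z["Xext"], Xinv=z["Xinv"], scales=z["scales"], P=task.P
            )
    return task, frame


def verify_manifest(output_dir: str | Path) -> list[str]:
    """Return the names of inventoried files whose checksum no longer matches."""
    out = Path(output_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    bad = []
    for name, digest in manifest["inventory"].items():
        p = out / name
        if not p.exists() or _sha256(p) != digest:
            bad.append(name)
    return bad
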