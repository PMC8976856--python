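"""Config serialisation and CSV/JSON writers.

Model specs round-trip through a nested mapping: constant rates are plain
numbers, regulated rates are tables of feedback fields.  TOML is the
primary config format (read with the standard library); JSON is accepted
interchangeably.  Trajectories export as tidy CSV ``t,S,D`` with
full-precision floats, and analysis reports as JSON with complex numbers
rendered as ``{"re": ..., "im": ...}`` pairs.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path
from typing import Any, Optional

import numpy as np

from .feedback import Feedback
from .model import ModelSpec
from .simulate import Trajectory

__all__ = [
    "spec_to_dict", "spec_from_dict",
    "read_config", "write_config", "dumps_toml",
    "write_trajectory_csv", "write_report_json", "jsonable",
]


# ------------------------------------------------------------ spec <-> dict

def spec_to_dict(spec: ModelSpec) -> dict:
    out: dict[str, Any] = {"topology": spec.topology}
    for name in ("beta", "omega", "delta"):
        val = getattr(spec, name)
        out[name] = val.to_dict() if isinstance(val, Feedback) else val
    if spec.rho is not None:
        out["rho"] = spec.rho.to_dict()
    return out


def spec_from_dict(mapping: dict) -> ModelSpec:
    kwargs: dict[str, Any] = {"topology": mapping.get("topology", "delta_of_D")}
    for name in ("beta", "omega", "delta", "rho"):
        if name not in mapping:
            continue
        val = mapping[name]
        kwargs[name] = Feedback.from_dict(val) if isinstance(val, dict) else float(val)
    return ModelSpec(**kwargs)


# ------------------------------------------------------------------- config

def read_config(path) -> dict:
    """Read a TOML (default) or JSON config file into a mapping."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())
    with path.open("rb") as fh:
        return tomllib.load(fh)


def _toml_scalar(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        # repr round-trips exactly and doubles as valid TOML (incl. inf/nan)
        return repr(float(value))
    if isinstance(value, str):
        return json.dumps(value)
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_scalar(v) for v in value) + "]"
    raise TypeError(f"cannot serialise {type(value).__name__} to TOML")


def dumps_toml(mapping: dict) -> str:
    """Serialise a nested mapping to TOML text with dotted table headers.

    Covers the scenario/config structures this package emits; not a
    general TOML writer (no arrays of tables).
    """
    lines: list[str] = []

    def emit(table: dict, prefix: str) -> None:
        scalars = {k: v for k, v in table.items() if not isinstance(v, dict)}
        subs = {k: v for k, v in table.items() if isinstance(v, dict)}
        if prefix and (scalars or not subs):
            lines.append("")
            lines.append(f"[{prefix}]")
        for k, v in scalars.items():
            lines.append(f"{k} = {_toml_scalar(v)}")
        for k, v in subs.items():
            emit(v, f"{prefix}.{k}" if prefix else k)

    emit(mapping, "")
    return "\n".join(lines).lstrip("\n") + "\n"


def write_config(mapping: dict, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(mapping, indent=2) + "\n")
    else:
        path.write_text(dumps_toml(mapping))


# ------------------------------------------------------------------ writers

def write_trajectory_csv(traj: Trajectory, path) -> None:
    """Tidy CSV ``t,S,D`` with repr-round-trip float precision."""
    lines = ["t,S,D"]
    for t, s, d in zip(traj.t, traj.S, traj.D):
        lines.append(f"{float(t)!r},{float(s)!r},{float(d)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def jsonable(obj):
    """Recursively convert reports/arrays/complex numbers for JSON output."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
                if not callable(getattr(obj, f.name))}
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    if isinstance(obj, np.ndarray):
        return [jsonable(x) for x in obj.tolist()]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, dict):
        return {k: jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [jsonable(x) for x in obj]
    return obj


def write_report_json(result, path, config: Optional[dict] = None) -> None:
    """Write an analysis result as JSON, embedding the resolved config."""
    payload = {"result": jsonable(result)}
    if config is not None:
        payload["config"] = jsonable(config)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
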