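"""Configuration schema, trace containers and summary output.

Configurations are YAML mappings validated against a typed schema (unknown
keys rejected, defaults filled).  Simulated traces are stored in HDF5 with
named datasets plus a delimited-text export; analysis summaries are JSON
documents carrying provenance (seed, package version, config hash).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, fields, is_dataclass

import h5py
import numpy as np
import yaml

from . import __version__
from .cable import SolverConfig, StateTrace, StimulusProtocol
from .montecarlo import MCLatencyConfig
from .morphology import GranuleCellParams
from .sbfi import NaKineticParams

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_and_validate",
    "dump_config",
    "save_trace",
    "load_trace",
    "export_trace_csv",
    "write_summary",
]


class ConfigError(ValueError):
    pass


_SECTION_TYPES = {
    "model": GranuleCellParams,
    "protocol": StimulusProtocol,
    "solver": SolverConfig,
    "sbfi": NaKineticParams,
    "mc_latency": MCLatencyConfig,
}


@dataclass
class RunConfig:
    model: GranuleCellParams = field(default_factory=GranuleCellParams)
    protocol: StimulusProtocol | None = None
    solver: SolverConfig = field(default_factory=SolverConfig)
    sbfi: NaKineticParams = field(default_factory=NaKineticParams)
    mc_latency: MCLatencyConfig = field(default_factory=MCLatencyConfig)
    seed: int = 0
    output_dir: str = "."
    log_level: str = "INFO"


def _coerce_section(cls, mapping: dict, where: str):
    valid = {f.name for f in fields(cls)}
    errors = [f"{where}.{k}: unknown key" for k in mapping if k not in valid]
    if errors:
        raise ConfigError("; ".join(errors))
    # tuples arrive from YAML as lists
    kwargs = {}
    for f in fields(cls):
        if f.name not in mapping:
            continue
        v = mapping[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{where}: {e}") from e


def load_and_validate(path) -> RunConfig:
    """Load a YAML run configuration, validate and fill defaults.

    Raises :class:`ConfigError` listing every violating key.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known = set(_SECTION_TYPES) | {"seed", "output_dir", "log_level"}
    unknown = [k for k in raw if k not in known]
    if unknown:
        raise ConfigError("; ".join(f"{k}: unknown key" for k in unknown))
    out = RunConfig()
    problems: list[str] = []
    for name, cls in _SECTION_TYPES.items():
        if name in raw:
            if raw[name] is None:
                continue
            if not isinstance(raw[name], dict):
                problems.append(f"{name}: must be a mapping")
                continue
            try:
                setattr(out, name, _coerce_section(cls, raw[name], name))
            except ConfigError as e:
                problems.append(str(e))
    if problems:
        raise ConfigError("; ".join(problems))
    out.seed = int(raw.get("seed", 0))
    out.output_dir = str(raw.get("output_dir", "."))
    out.log_level = str(raw.get("log_level", "INFO"))
    return out


def dump_config(config: RunConfig) -> str:
    """Serialize a run configuration to normalized YAML."""

    def to_plain(obj):
        if is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: to_plain(getattr(obj, f.name)) for f in fields(obj)
                    if not f.name.startswith("_")}
        if isinstance(obj, tuple):
            return [to_plain(v) for v in obj]
        return obj

    doc = {
        "model": to_plain(config.model),
        "protocol": to_plain(config.protocol) if config.protocol else None,
        "solver": to_plain(config.solver),
        "sbfi": to_plain(config.sbfi),
        "mc_latency": to_plain(config.mc_latency),
        "seed": config.seed,
        "output_dir": config.output_dir,
        "log_level": config.log_level,
    }
    return yaml.safe_dump(doc, sort_keys=True)


# ---------------------------------------------------------------------------
# Trace container I/O
# ---------------------------------------------------------------------------


def save_trace(trace: StateTrace, path) -> None:
    """Write a StateTrace to an HDF5 container with named datasets."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("time_ms", data=trace.t)
        h5.create_dataset("v_mV", data=trace.v)
        h5.create_dataset("distance_um", data=trace.dist_um)
        h5.create_dataset("kind_code", data=trace.kind_code)
        h5.create_dataset(
            "section_id", data=np.array(trace.section_id, dtype="S32")
        )
        for name, arr in trace.currents.items():
            h5.create_dataset(f"i_{name}_mA_cm2", data=arr)
        for name, arr in trace.gates.items():
            h5.create_dataset(f"gate_{name}", data=arr)
        for k, v in trace.meta.items():
            h5.attrs[k] = v


def load_trace(path) -> StateTrace:
    with h5py.File(path, "r") as h5:
        currents = {}
        gates = {}
        for name in h5:
            if name.startswith("i_") and name.endswith("_mA_cm2"):
                currents[name[2:-7]] = h5[name][...]
            elif name.startswith("gate_"):
                gates[name[5:]] = h5[name][...]
        return StateTrace(
            t=h5["time_ms"][...],
            v=h5["v_mV"][...],
            dist_um=h5["distance_um"][...],
            kind_code=h5["kind_code"][...],
            section_id=[s.decode() for s in h5["section_id"][...]],
            currents=currents,
            gates=gates,
            meta=dict(h5.attrs),
        )


def export_trace_csv(trace: StateTrace, path, sites_um=(0.0, 25.0, 100.0)) -> None:
    """Delimited-text export of the voltage at selected axonal distances."""
    import pandas as pd

    cols = {"time_ms": trace.t}
    soma = trace.soma_index()
    cols["v_soma_mV"] = trace.v[:, soma]
    for d in sites_um:
        i = trace.site_index(d)
        cols[f"v_axon_{trace.dist_um[i]:.1f}um_mV"] = trace.v[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_summary(results: dict, path, seed: int | None = None,
                  config: RunConfig | None = None) -> dict:
    """Write a machine-readable summary with provenance; returns the document."""
    doc = {
        "provenance": {
            "package": "axinit",
            "version": __version__,
            "seed": seed,
        },
        "results": _jsonable(results),
    }
    if config is not None:
        doc["provenance"]["config_sha256"] = hashlib.sha256(
            dump_config(config).encode()
        ).hexdigest()
    tmp = str(path) + ".tmp"
    with open(tmp, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)
    return doc


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in fields(obj)}
    return obj
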