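"""Configuration, trace, and manifest I/O.

Formats: YAML (or JSON) configuration snapshots, CSV time series with a
``time_ms`` column, HDF5 for full multicompartment dumps, JSON for analysis
summaries and run manifests.  A manifest records every parameter, flag, seed
and output checksum needed to re-execute a run bit-compatibly on the same
platform.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calcium import CalciumParams
from .channels import NavParams
from .engine import Model, Protocol, SimulationResult, assemble
from .morphology import GradientRules, apply_gradients, build_reduced_morphology
from .synthetic import RampSpec

__all__ = [
    "model_config",
    "model_from_config",
    "load_config",
    "save_config",
    "write_trace_csv",
    "read_trace_csv",
    "write_result_h5",
    "write_spike_times_csv",
    "RunManifest",
    "file_checksum",
]

_MORPH_KEYS = (
    "soma_diameter", "trunk_length", "trunk_diameter", "trunk_segments",
    "basal_length", "basal_diameter", "basal_segments",
    "spine_factor", "R_m", "R_a", "C_m",
)


def model_config(
    morphology_kwargs: dict | None = None,
    base_densities: dict | None = None,
    rules: GradientRules | None = None,
    nav_params: NavParams | None = None,
    ca_params: CalciumParams | None = None,
) -> dict:
    """Structured config dict fully describing a model (defaults filled in)."""
    return {
        "morphology": dict(morphology_kwargs or {}),
        "densities": dict(base_densities or {}),
        "gradients": dataclasses.asdict(rules or GradientRules()),
        "nav": dataclasses.asdict(nav_params or NavParams()),
        "calcium": dataclasses.asdict(ca_params or CalciumParams()),
    }


def model_from_config(config: dict) -> Model:
    """Build a model from a config dict (as produced by :func:`model_config`)."""
    morph_kwargs = {k: v for k, v in config.get("morphology", {}).items() if k in _MORPH_KEYS}
    morph = build_reduced_morphology(**morph_kwargs)
    rules = GradientRules(**config.get("gradients", {}))
    dens = apply_gradients(morph, config.get("densities") or None, rules)
    nav = NavParams(**config.get("nav", {}))
    ca = CalciumParams(**config.get("calcium", {}))
    return assemble(morph, dens, nav, ca)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(config: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True))


def write_trace_csv(path: str | Path, time_ms: np.ndarray, columns: dict) -> None:
    """CSV time series: a ``time_ms`` column plus named value columns."""
    frame = pd.DataFrame({"time_ms": np.asarray(time_ms), **columns})
    frame.to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "time_ms" not in frame.columns:
        raise ValueError(f"{path}: trace CSV must contain a 'time_ms' column")
    return frame


def write_result_h5(path: str | Path, result: SimulationResult) -> None:
    """Full multicompartment dump (voltages, nanodomain Ca, soma traces)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("time_ms", data=result.time, compression="gzip")
        f.create_dataset("v_mV", data=result.v, compression="gzip")
        f.create_dataset("ca_nd_uM", data=result.cand, compression="gzip")
        f.create_dataset("soma_traces", data=result.soma, compression="gzip")
        f.create_dataset("injected_nA", data=result.injected, compression="gzip")
        f.attrs["dt_ms"] = result.dt
        f.attrs["holding_current_nA"] = result.holding_current
        f.attrs["mode"] = result.protocol.mode
        f.attrs["freeze_voltage"] = result.protocol.freeze_voltage
        f.attrs["version"] = __version__


def write_spike_times_csv(path: str | Path, spike_times: np.ndarray) -> None:
    pd.DataFrame({"spike_time_ms": np.asarray(spike_times)}).to_csv(path, index=False)


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Everything needed to re-execute a run and verify its outputs."""

    config: dict
    protocol: dict
    seed: int
    dt: float
    version: str
    outputs: dict[str, str]  # filename -> sha256

    @classmethod
    def for_run(
        cls,
        config: dict,
        protocol: Protocol,
        output_paths: list[str | Path],
    ) -> "RunManifest":
        proto = {
            "hold_V": protocol.hold_V,
            "equilibration_ms": protocol.equilibration,
            "mode": protocol.mode,
            "freeze_voltage": protocol.freeze_voltage,
            "dt_ms": protocol.dt,
            "seed": protocol.seed,
            "ramp": dataclasses.asdict(protocol.ramp) if protocol.ramp else None,
        }
        return cls(
            config=config,
            protocol=proto,
            seed=protocol.seed,
            dt=protocol.dt,
            version=__version__,
            outputs={str(Path(p).name): file_checksum(p) for p in output_paths},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
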