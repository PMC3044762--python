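"""Configuration, manifests, and file I/O.

A run is fully described by a structured-text configuration (YAML/JSON)
whose sections mirror the package's config dataclasses; unknown sections
or keys are rejected by name.  Every output directory carries a manifest
recording the fully resolved configuration, the seeds of each randomness
source, and a checksum inventory of the files written, so that re-running
a stage from its manifest reproduces identical bytes.

Formats: CSV for spike records, per-cell tables and logs; Matrix Market
(MTX) for weight blocks; JSON for metrics and the manifest itself.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .decision import RewardRuleConfig, UrgencyConfig
from .dynamics import IntegrationConfig, NoiseConfig, SpikeRecord, SynapseKinetics
from .network_builder import NetworkConfig, NetworkInstance
from .plasticity import (HomeostasisConfig, LTPiConfig, PairSTDPConfig,
                         TripletSTDPConfig)
from .protocol import ConditionSpec


class ConfigError(ValueError):
    pass


_SECTIONS = {
    "network": NetworkConfig,
    "integration": IntegrationConfig,
    "kinetics": SynapseKinetics,
    "noise": NoiseConfig,
    "condition": ConditionSpec,
    "homeostasis": HomeostasisConfig,
    "pair_stdp": PairSTDPConfig,
    "triplet_stdp": TripletSTDPConfig,
    "ltpi": LTPiConfig,
    "reward": RewardRuleConfig,
    "urgency": UrgencyConfig,
}


@dataclass
class RunConfig:
    """All sections resolved to dataclasses, defaults filled in."""

    network: NetworkConfig
    integration: IntegrationConfig
    kinetics: SynapseKinetics
    noise: NoiseConfig
    condition: ConditionSpec
    homeostasis: HomeostasisConfig
    pair_stdp: PairSTDPConfig
    triplet_stdp: TripletSTDPConfig
    ltpi: LTPiConfig
    reward: RewardRuleConfig
    urgency: UrgencyConfig

    def to_dict(self) -> dict:
        return {name: dataclasses.asdict(getattr(self, name))
                for name in _SECTIONS}


def _build_section(name: str, cls, values: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - fields
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {name!r}; "
            f"allowed: {sorted(fields)}")
    try:
        return cls(**values)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in section {name!r}: {exc}") from exc


def resolve_config(raw: Optional[dict]) -> RunConfig:
    """Validate a raw mapping against the schema; missing sections and keys
    take their defaults (an empty mapping resolves to the standard regime)."""
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(
            f"unknown section(s) {sorted(unknown)}; allowed: {sorted(_SECTIONS)}")
    sections = {}
    for name, cls in _SECTIONS.items():
        values = raw.get(name, {}) or {}
        if not isinstance(values, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        sections[name] = _build_section(name, cls, values)
    return RunConfig(**sections)


def load_config(path) -> RunConfig:
    """Load and schema-validate a YAML (or JSON) run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return resolve_config(raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# artifact writers

def write_spikes_csv(record: SpikeRecord, path) -> None:
    pd.DataFrame({"trial": record.trial, "population": record.population,
                  "neuron_id": record.ids,
                  "time_ms": record.times}).to_csv(path, index=False)


def read_spikes_csv(path) -> SpikeRecord:
    df = pd.read_csv(path)
    duration = float(df["time_ms"].max()) if len(df) else 0.0
    pop = str(df["population"].iloc[0]) if len(df) else ""
    trial = int(df["trial"].iloc[0]) if len(df) else 0
    return SpikeRecord(df["neuron_id"].to_numpy(dtype=np.int64),
                       df["time_ms"].to_numpy(dtype=float), pop, duration, trial)


def write_weights_mtx(weights: np.ndarray, path) -> None:
    scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(weights))


def read_weights_mtx(path) -> np.ndarray:
    return np.asarray(scipy.io.mmread(str(path)).todense())


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_voltage_h5(traces: np.ndarray, path, dt: float) -> None:
    """Optional HDF5 container for voltage traces (n_steps, n_cells)."""
    import h5py
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("voltage_mv", data=traces, compression="gzip")
        ds.attrs["dt_ms"] = dt


def read_voltage_h5(path):
    import h5py
    with h5py.File(path, "r") as fh:
        return fh["voltage_mv"][...], float(fh["voltage_mv"].attrs["dt_ms"])


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Resolved configuration + seeds + checksummed file inventory."""

    config: dict
    seeds: dict
    inventory: dict  # relative path -> sha256
    stage: str = ""
    version: str = "pairnet-0.1.0"

    def to_dict(self) -> dict:
        return {"stage": self.stage, "version": self.version,
                "config": self.config, "seeds": self.seeds,
                "inventory": self.inventory}


def write_outputs(out_dir, stage: str, config: RunConfig, seeds: dict,
                  artifacts: dict) -> RunManifest:
    """Write a stage's artifacts and its manifest.

    ``artifacts`` maps relative filename -> object; the writer is picked by
    extension: .csv takes a DataFrame or SpikeRecord, .mtx a weight array,
    .json any JSON-serializable object.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory = {}
    for rel, obj in artifacts.items():
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        if rel.endswith(".csv"):
            if isinstance(obj, SpikeRecord):
                write_spikes_csv(obj, path)
            else:
                obj.to_csv(path, index=False)
        elif rel.endswith(".mtx"):
            write_weights_mtx(obj, path)
        elif rel.endswith(".json"):
            write_json(obj, path)
        else:
            raise ConfigError(f"no writer for artifact {rel!r}")
        inventory[rel] = file_checksum(path)
    manifest = RunManifest(config.to_dict(), seeds, inventory, stage)
    write_json(manifest.to_dict(), out / "manifest.json")
    return manifest


def read_manifest(out_dir) -> RunManifest:
    with open(Path(out_dir) / "manifest.json") as fh:
        d = json.load(fh)
    return RunManifest(d["config"], d["seeds"], d["inventory"],
                       d.get("stage", ""), d.get("version", ""))


def verify_outputs(out_dir) -> bool:
    """Re-checksum every file in the manifest inventory."""
    manifest = read_manifest(out_dir)
    out = Path(out_dir)
    return all(file_checksum(out / rel) == digest
               for rel, digest in manifest.inventory.items())


def save_network(network: NetworkInstance, out_dir) -> RunManifest:
    """Serialize a built network: weight blocks as MTX, cell parameter
    tables as CSV, plus the manifest naming blocks and seeds."""
    artifacts = {"params_e.csv": network.params_e,
                 "params_i.csv": network.params_i}
    for name, blk in network.blocks.items():
        artifacts[f"weights_{name}.mtx"] = blk.weights
    config = resolve_config({"network": dataclasses.asdict(network.config)})
    return write_outputs(out_dir, "build", config, network.seeds, artifacts)
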