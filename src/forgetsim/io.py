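"""Serialization: result CSVs, config files, run manifests."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import RetentionCurve
from .distributions import DistributionSpec
from .experiment import (
    AlwaysRetained,
    FatigueEncoding,
    InterferenceMemory,
    NeverRetained,
    PerfectEncoding,
    ProtocolConfig,
)
from .simulate import SURVIVED, SimulationConfig, SimulationResult

__all__ = [
    "simulation_to_frames",
    "save_simulation",
    "load_simulation",
    "curve_to_frame",
    "load_config_file",
    "simulation_config_from_dict",
    "simulation_config_to_dict",
    "protocol_config_from_dict",
    "protocol_config_to_dict",
    "write_manifest",
]


def simulation_to_frames(result: SimulationResult):
    """Items and store-size trajectory as two DataFrames.

    Items carry an empty erasure_time for survivors; the trajectory frame
    has one row per step.
    """
    erasure = pd.array(result.erasure_time, dtype="Int64")
    erasure[result.erasure_time == SURVIVED] = pd.NA
    items = pd.DataFrame(
        {
            "item_id": np.arange(result.T),
            "acquisition_time": result.acquisition_time,
            "erasure_time": erasure,
            "n_dims": result.n_dims,
            "seed": result.seed if result.seed is not None else pd.NA,
        }
    )
    store = pd.DataFrame(
        {"step": np.arange(1, result.T + 1), "store_size": result.store_size}
    )
    return items, store


def save_simulation(result: SimulationResult, items_path, store_path) -> None:
    items, store = simulation_to_frames(result)
    items.to_csv(items_path, index=False)
    store.to_csv(store_path, index=False)


def load_simulation(items_path, store_path, variant="full_erasure") -> SimulationResult:
    items = pd.read_csv(items_path)
    store = pd.read_csv(store_path)
    erasure = items["erasure_time"].fillna(SURVIVED).to_numpy(dtype=np.int64)
    seed_col = items["seed"]
    seed = None if seed_col.isna().all() else int(seed_col.iloc[0])
    return SimulationResult(
        variant=variant,
        n_dims=int(items["n_dims"].iloc[0]),
        T=len(items),
        seed=seed,
        acquisition_time=items["acquisition_time"].to_numpy(dtype=np.int64),
        erasure_time=erasure,
        store_size=store["store_size"].to_numpy(dtype=np.int64),
        valences=None,
    )


def curve_to_frame(curve: RetentionCurve) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lag": curve.lags,
            "value": curve.values,
            "method": curve.method,
            "n_dims": curve.n_dims if curve.n_dims is not None else pd.NA,
        }
    )


def load_config_file(path) -> dict:
    """Load a JSON or YAML config by file suffix."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _dist_dict(dist_or_spec) -> dict:
    if isinstance(dist_or_spec, DistributionSpec):
        return dist_or_spec.to_dict()
    # frozen scipy distribution
    dist = getattr(dist_or_spec, "dist", None)
    if dist is not None:
        return {
            "name": dist.name,
            "params": dict(
                zip(
                    list(dist.shapes.split(", ") if dist.shapes else [])
                    + ["loc", "scale"],
                    list(dist_or_spec.args) + list(dist_or_spec.kwds.values()),
                )
            )
            if dist_or_spec.args or dist_or_spec.kwds
            else {},
        }
    value = getattr(dist_or_spec, "value", None)
    if value is not None:
        return {"name": "constant", "params": {"value": value}}
    raise TypeError(f"cannot serialize distribution {dist_or_spec!r}")


def simulation_config_to_dict(config: SimulationConfig) -> dict:
    out = {
        "variant": config.variant,
        "T": config.T,
        "n_dims": config.n_dims,
        "seed": config.seed,
    }
    if config.variant == "linear_decay":
        out["strength_distribution"] = _dist_dict(config.strength_distribution)
        out["decay_distribution"] = _dist_dict(config.decay_distribution)
    else:
        out["distribution"] = _dist_dict(config.valence_distribution)
    return out


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    kwargs = dict(
        variant=d["variant"],
        T=d["T"],
        n_dims=d.get("n_dims", 1),
        seed=d.get("seed", 0),
    )
    if "distribution" in d:
        kwargs["valence_distribution"] = DistributionSpec.from_any(d["distribution"])
    if "strength_distribution" in d:
        kwargs["strength_distribution"] = DistributionSpec.from_any(
            d["strength_distribution"]
        )
    if "decay_distribution" in d:
        kwargs["decay_distribution"] = DistributionSpec.from_any(
            d["decay_distribution"]
        )
    return SimulationConfig(**kwargs)


_ENCODINGS = {"perfect": PerfectEncoding, "fatigue": FatigueEncoding}
_MEMORIES = {
    "interference": InterferenceMemory,
    "always_retained": AlwaysRetained,
    "never_retained": NeverRetained,
}


def protocol_config_to_dict(config: ProtocolConfig) -> dict:
    enc = {"kind": config.encoding.kind}
    if isinstance(config.encoding, FatigueEncoding):
        enc["gamma"] = config.encoding.gamma
    mem = {"kind": config.memory.kind}
    if isinstance(config.memory, InterferenceMemory):
        mem["n_dims"] = config.memory.n_dims
    return {
        "n_participants": config.n_participants,
        "stream_length": config.stream_length,
        "n_2back": config.n_2back,
        "n_10back": config.n_10back,
        "n_early": config.n_early,
        "pool_size": config.pool_size,
        "encoding": enc,
        "memory": mem,
        "seed": config.seed,
    }


def protocol_config_from_dict(d: dict) -> ProtocolConfig:
    enc = dict(d.get("encoding", {"kind": "perfect"}))
    mem = dict(d.get("memory", {"kind": "interference"}))
    encoding = _ENCODINGS[enc.pop("kind")](**enc)
    memory = _MEMORIES[mem.pop("kind")](**mem)
    return ProtocolConfig(
        n_participants=d["n_participants"],
        stream_length=d.get("stream_length", 500),
        n_2back=d.get("n_2back", 25),
        n_10back=d.get("n_10back", 25),
        n_early=d.get("n_early", 25),
        pool_size=d.get("pool_size", 751),
        encoding=encoding,
        memory=memory,
        seed=d.get("seed", 0),
    )


def write_manifest(path, command: str, config: dict, seed, outputs) -> dict:
    """Write a JSON run manifest referencing every produced output file."""
    manifest = {
        "command": command,
        "package_version": __version__,
        "seed": seed,
        "config": config,
        "outputs": [str(p) for p in outputs],
        "created": datetime.now(timezone.utc).isoformat(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
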