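"""Configuration loading, presets, seed derivation, and run manifests.

Configs are plain YAML/JSON mappings with two sections, ``network`` and
``training``, validated into :class:`~adnet.network.NetworkSpec` and
:class:`~adnet.model.TrainConfig`.  Two named presets reproduce the reference
architectures:

``cl-permuted``
    The continual-learning network for permuted image streams: 784 inputs,
    two hidden layers of 2048, a single 10-unit head, 50% feedforward weight
    sparsity, 5% activation density, one dendritic segment per task (default
    T=10) with 784 weights each, both hidden layers modulated.
``mt10-policy``
    The multi-task RL policy trunk: 39 inputs, two hidden layers of 2800, 4
    outputs, 10% weight sparsity, 25% activation density, kWTA on both hidden
    layers, 10 segments of 10 weights on the second hidden layer only
    (one-hot task contexts).

All randomness flows from one master seed; component sub-seeds are derived by
a counter-based spawn scheme so adding a component never perturbs the streams
of existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .exceptions import ConfigurationError
from .model import TrainConfig, default_hyperparams
from .network import NetworkSpec

__all__ = [
    "PRESETS",
    "preset_spec",
    "load_config",
    "derive_seed",
    "RunManifest",
]


def preset_spec(name: str, n_tasks: int = 10) -> NetworkSpec:
    """Instantiate a named architecture preset."""
    if name == "cl-permuted":
        return NetworkSpec(
            input_dim=784,
            hidden_dims=(2048, 2048),
            output_dim=10,
            context_dim=784,
            weight_sparsity=0.5,
            activation_density=0.05,
            num_segments=n_tasks,
            segment_dim=784,
            modulated_layers=(0, 1),
            gating_mode="absolute_max",
            kwta_layers=(0, 1),
        )
    if name == "mt10-policy":
        return NetworkSpec(
            input_dim=39,
            hidden_dims=(2800, 2800),
            output_dim=4,
            context_dim=10,
            weight_sparsity=0.10,
            activation_density=0.25,
            num_segments=10,
            segment_dim=10,
            modulated_layers=(1,),
            gating_mode="absolute_max",
            kwta_layers=(0, 1),
        )
    raise ConfigurationError(f"unknown preset {name!r}")


PRESETS = ("cl-permuted", "mt10-policy")

_SPEC_KEYS = {f.name for f in dataclasses.fields(NetworkSpec)}
_TRAIN_KEYS = {f.name for f in dataclasses.fields(TrainConfig)}


def load_config(path) -> tuple[NetworkSpec, TrainConfig]:
    """Load and validate a YAML/JSON config file.

    Layout: optional top-level ``preset`` (with optional ``n_tasks``), a
    ``network`` mapping overriding :class:`NetworkSpec` fields, and a
    ``training`` mapping overriding :class:`TrainConfig` fields.  Unknown keys
    are reported by name.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")

    known_top = {"preset", "n_tasks", "network", "training"}
    for key in raw:
        if key not in known_top:
            raise ConfigurationError(f"unknown top-level config key {key!r}")

    net_over = dict(raw.get("network") or {})
    train_over = dict(raw.get("training") or {})
    for key in net_over:
        if key not in _SPEC_KEYS:
            raise ConfigurationError(f"unknown network config key {key!r}")
    for key in train_over:
        if key not in _TRAIN_KEYS:
            raise ConfigurationError(f"unknown training config key {key!r}")

    n_tasks = int(raw.get("n_tasks", 10))
    if raw.get("preset"):
        base = dataclasses.asdict(preset_spec(raw["preset"], n_tasks=n_tasks))
        base.update(net_over)
        for key in ("hidden_dims", "modulated_layers", "kwta_layers"):
            if base.get(key) is not None:
                base[key] = tuple(base[key])
        spec = NetworkSpec(**base)
        lr, epochs = default_hyperparams(
            n_tasks, train_over.get("context_mode", "prototype_given")
        )
        train = {"learning_rate": lr, "epochs_per_task": epochs}
        train.update(train_over)
    else:
        if "hidden_dims" in net_over:
            net_over["hidden_dims"] = tuple(net_over["hidden_dims"])
        for key in ("modulated_layers", "kwta_layers"):
            if net_over.get(key) is not None:
                net_over[key] = tuple(net_over[key])
        spec = NetworkSpec(**net_over)
        train = train_over
    return spec, TrainConfig(**train)


def derive_seed(master_seed: int, label: str) -> int:
    """Stable per-component sub-seed (counter-based; independent across labels)."""
    digest = hashlib.sha256(label.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    ss = np.random.SeedSequence(master_seed, spawn_key=(key,))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


@dataclass
class RunManifest:
    """Snapshot sufficient to reproduce a run bit-for-bit."""

    config: dict
    master_seed: int
    sub_seeds: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    version: str = __version__

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "master_seed": self.master_seed,
                    "sub_seeds": self.sub_seeds,
                    "artifacts": self.artifacts,
                    "version": self.version,
                    "config_hash": self.config_hash(),
                },
                fh,
                indent=2,
                default=str,
            )

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            config=d["config"],
            master_seed=d["master_seed"],
            sub_seeds=d.get("sub_seeds", {}),
            artifacts=d.get("artifacts", {}),
            version=d.get("version", __version__),
        )
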