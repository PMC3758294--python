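"""Experiment configuration: JSON loading, validation and provenance.

A configuration file is a flat JSON object whose keys are the model
parameters (:class:`~latchnet.params.ModelParams` fields) plus the
experiment-level settings ``n_items``, ``n_trials``, ``base_seed`` and
``blocked``.  An empty object resolves to the model's published operating
point and the standard 12-item protocol.  Unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, fields
from pathlib import Path

from .params import ModelParams

__all__ = ["ExperimentConfig", "load_config", "save_config", "config_hash"]

_PARAM_FIELDS = {f.name for f in fields(ModelParams)}


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved experiment configuration (model + protocol + run plan)."""

    params: ModelParams = ModelParams()
    n_items: int = 12
    n_trials: int = 1024
    base_seed: int = 0
    blocked: bool = False

    def validate(self) -> None:
        self.params.validate()
        if self.n_items < 1:
            raise ValueError(f"n_items must be >= 1, got {self.n_items}")
        if self.n_trials < 1:
            raise ValueError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.base_seed < 0:
            raise ValueError(f"base_seed must be >= 0, got {self.base_seed}")
        for name in ("item_clamp_s", "isi_s", "recall_s"):
            dur = getattr(self.params, name)
            if not math.isclose(round(dur / self.params.dt)
                                * self.params.dt, dur, rel_tol=0.0,
                                abs_tol=1e-9):
                raise ValueError(
                    f"{name}={dur} is not a multiple of dt="
                    f"{self.params.dt}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.params)
        d.update(n_items=self.n_items, n_trials=self.n_trials,
                 base_seed=self.base_seed, blocked=self.blocked)
        return d

    def replace(self, **changes) -> "ExperimentConfig":
        """Copy with changes; model-parameter names are routed into the
        nested :class:`ModelParams`."""
        pchanges = {k: v for k, v in changes.items() if k in _PARAM_FIELDS}
        echanges = {k: v for k, v in changes.items()
                    if k not in _PARAM_FIELDS}
        cfg = self
        if pchanges:
            cfg = dataclasses.replace(cfg, params=cfg.params.replace(
                **pchanges))
        if echanges:
            cfg = dataclasses.replace(cfg, **echanges)
        cfg.validate()
        return cfg


def config_from_dict(data: dict) -> ExperimentConfig:
    exp_fields = {"n_items", "n_trials", "base_seed", "blocked"}
    unknown = set(data) - _PARAM_FIELDS - exp_fields
    if unknown:
        raise ValueError(
            f"unknown configuration key(s): {sorted(unknown)}")
    try:
        params = ModelParams(**{k: v for k, v in data.items()
                                if k in _PARAM_FIELDS})
    except TypeError as exc:  # pragma: no cover - defensive
        raise ValueError(str(exc)) from exc
    cfg = ExperimentConfig(
        params=params,
        **{k: data[k] for k in exp_fields if k in data})
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a JSON configuration file; missing keys take the
    documented defaults, unknown keys raise ``ValueError`` naming them."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a JSON object")
    return config_from_dict(data)


def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def config_hash(cfg: ExperimentConfig) -> str:
    """Short stable hash of the fully resolved configuration, stamped on
    every output file for provenance."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
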