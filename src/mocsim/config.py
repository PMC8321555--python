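"""Plain-text (YAML) configuration for experiments.

A config file holds any subset of the experiment and neuron parameters;
missing keys fall back to the package defaults.  Example::

    experiment:
      n_inputs: 20
      rate_paradigm: high
      plasticity: depressing
      n_instances: 6
      seed: 1
      combine_with:
        n_inputs: 20
        rate_paradigm: mid
        plasticity: facilitating
    neuron:
      v_thresh: -71.37
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .errors import InvalidParameterError
from .experiments import ParadigmConfig
from .neuron import NeuronParams

__all__ = ["load_config", "experiment_from_config"]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise InvalidParameterError(f"config root must be a mapping, got {type(cfg).__name__}")
    return cfg


def _neuron_params(section: dict | None) -> NeuronParams:
    section = section or {}
    valid = {f.name for f in fields(NeuronParams)}
    unknown = set(section) - valid
    if unknown:
        raise InvalidParameterError(f"unknown neuron parameter(s): {sorted(unknown)}")
    return NeuronParams(**section)


def experiment_from_config(cfg: dict, seed: int | None = None) -> ParadigmConfig:
    """Build a ParadigmConfig from a loaded config dict; ``seed`` overrides."""
    exp = dict(cfg.get("experiment") or {})
    if not exp:
        raise InvalidParameterError("config has no 'experiment' section")
    sub = exp.pop("combine_with", None)
    if sub is not None:
        sub = ParadigmConfig(base_params=_neuron_params(cfg.get("neuron")), **sub)
    if seed is not None:
        exp["seed"] = seed
    return ParadigmConfig(
        combine_with=sub, base_params=_neuron_params(cfg.get("neuron")), **exp
    )
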