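"""Run configuration: YAML/JSON loading, validation, and echoing.

Config keys mirror the published parameter names one-to-one (``p_G1``,
``p_Cdh1`` ... ``f_CV``, ``mu``); ``mdt`` may be given instead of ``mu``
(mass-doubling time in minutes, converted as mu = ln2/mdt).  A ``ruleset``
block selects a strain label or declares inline rule overrides; ``seed``
sets the root random seed.  Unknown keys are rejected.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, fields

import yaml

from .params import Parameters
from .rules import WILD_TYPE, RuleSet, ruleset_from_config

_PARAM_NAMES = {f.name for f in fields(Parameters)}
_TOP_KEYS = {"parameters", "ruleset", "seed", "experiment"}


@dataclass
class RunConfig:
    """Fully resolved run configuration."""

    params: Parameters = field(default_factory=Parameters)
    rules: RuleSet = WILD_TYPE
    seed: int = 0
    experiment: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "parameters": self.params.to_dict(),
            "ruleset": {
                "label": self.rules.label,
                "rules": dict(self.rules.expressions),
                "parameters": dict(self.rules.parameter_overrides),
            },
            "seed": self.seed,
            "experiment": dict(self.experiment),
        }


def _parse_parameters(block: dict) -> Parameters:
    block = dict(block)
    mdt = block.pop("mdt", None)
    unknown = set(block) - _PARAM_NAMES
    if unknown:
        raise ValueError(f"unknown parameter key(s): {sorted(unknown)}")
    if mdt is not None and "mu" in block:
        raise ValueError("give either mu or mdt, not both")
    params = Parameters(**block)
    if mdt is not None:
        params = params.with_mass_doubling_time(float(mdt))
    return params


def load_config(path: str | None = None, data: dict | None = None) -> RunConfig:
    """Load and validate a config file (YAML or JSON; empty file = defaults)."""
    if data is None:
        if path is None:
            return RunConfig()
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    params = _parse_parameters(data.get("parameters", {}))
    rules = (ruleset_from_config(data["ruleset"])
             if "ruleset" in data else WILD_TYPE)
    seed = int(data.get("seed", 0))
    experiment = data.get("experiment", {})
    if not isinstance(experiment, dict):
        raise ValueError("experiment block must be a mapping")
    return RunConfig(params=params, rules=rules, seed=seed,
                     experiment=dict(experiment))


def echo_config(config: RunConfig, out_path: str) -> str:
    """Write the fully resolved config next to an output file.

    Returns the path written (``<out_path>.config.json``).
    """
    echo_path = f"{out_path}.config.json"
    with open(echo_path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return echo_path
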