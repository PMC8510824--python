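"""YAML/JSON configuration glue.

A config file mirrors the library's dataclasses section by section::

    normalize: {divisor: sd, missing_threshold: 0.2, impute_k: 5}
    gggp:      {population_size: 30, generations: 20, crossover_prob: 0.8,
                mutation_prob: 0.2, tournament_size: 3, max_depth: 5}
    pso:       {swarm_size: 30, iterations: 50, inertia: 0.729,
                c1: 1.49445, c2: 1.49445, v_max: 4.0}
    training:  {outer_rounds: 3}
    cascade:   {K: 5, max_layers: 5, min_gain: 0.005, patience: 1,
                validation_fraction: 0.25, weights: normalized,
                train_on: uncertain,
                region: {low: 0.2, high: 0.8},
                function_sets: [[2,3,4], [2,3,5], [2,4,5]]}

Any omitted key falls back to the library default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cascade import CascadeConfig, ConfidenceRegion
from .evolution import GGGPConfig
from .fnt import FunctionSet
from .pso import PSOConfig

__all__ = ["PreprocessConfig", "load_config", "cascade_config_from_dict"]


@dataclass
class PreprocessConfig:
    divisor: str = "sd"
    missing_threshold: float = 0.20
    impute_k: int = 5


def cascade_config_from_dict(d: dict) -> CascadeConfig:
    gggp = GGGPConfig(**d.get("gggp", {}))
    pso = PSOConfig(**d.get("pso", {}))
    c = dict(d.get("cascade", {}))
    region = ConfidenceRegion(**c.pop("region", {}))
    fsets = c.pop("function_sets", None)
    kwargs = dict(c)
    if fsets is not None:
        kwargs["function_sets"] = tuple(FunctionSet(tuple(fs)) for fs in fsets)
    training = d.get("training", {})
    return CascadeConfig(
        gggp=gggp,
        pso=pso,
        region=region,
        outer_rounds=int(training.get("outer_rounds", 3)),
        **kwargs,
    )


def load_config(path: str | Path | None) -> tuple[CascadeConfig, PreprocessConfig]:
    """Read a YAML config file; a missing path yields all defaults."""
    if path is None:
        return CascadeConfig(), PreprocessConfig()
    d = yaml.safe_load(Path(path).read_text()) or {}
    pre = PreprocessConfig(**d.get("normalize", {}))
    return cascade_config_from_dict(d), pre
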