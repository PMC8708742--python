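"""Run configuration: hyperparameters, grids, and YAML loading.

Defaults follow the reference operating point for fed-batch fermentation
soft sensing: an NCL ensemble of 5 ELMs with 20 hidden nodes and trade-off
0.6; M = 3 learners over a 300-sample unlabeled subsample; GA population
and generations of 50; trade-off-weight candidate set {0, 0.01, 0.1, 0.5, 1}
per weight (125 settings, 375 base models); pruning threshold 0; 95 %
confidence bounds.  Any of these can be overridden from a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .pseudolabel import GAConfig

DEFAULT_GAMMA_CANDIDATES = (0.0, 0.01, 0.1, 0.5, 1.0)


@dataclass(frozen=True)
class ModelHyper:
    n_elm: int = 5
    n_node: int = 20
    lam: float = 0.6


@dataclass(frozen=True)
class PLOSettings:
    m: int = 3
    u_prime: int = 300
    delta: float | str = "knn"
    ci_level: float = 0.95
    gamma1_grid: tuple[float, ...] = DEFAULT_GAMMA_CANDIDATES
    gamma2_grid: tuple[float, ...] = DEFAULT_GAMMA_CANDIDATES
    gamma3_grid: tuple[float, ...] = DEFAULT_GAMMA_CANDIDATES


@dataclass(frozen=True)
class RunConfig:
    model: ModelHyper = field(default_factory=ModelHyper)
    plo: PLOSettings = field(default_factory=PLOSettings)
    ga: GAConfig = field(default_factory=GAConfig)
    pir_threshold: float = 0.0
    max_components: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw or {})
    model = ModelHyper(**raw.get("model", {}))
    plo_raw = dict(raw.get("plo", {}))
    for key in ("gamma1_grid", "gamma2_grid", "gamma3_grid"):
        if key in plo_raw:
            plo_raw[key] = tuple(plo_raw[key])
    plo = PLOSettings(**plo_raw)
    ga = GAConfig(**raw.get("ga", {}))
    return RunConfig(
        model=model,
        plo=plo,
        ga=ga,
        pir_threshold=float(raw.get("pir_threshold", 0.0)),
        max_components=int(raw.get("max_components", 10)),
        seed=int(raw.get("seed", 0)),
    )


def load_config(path) -> RunConfig:
    """Read a (possibly partial) YAML config, filling defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return config_from_dict(raw)
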