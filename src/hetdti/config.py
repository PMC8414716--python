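"""Run configuration: one YAML document carrying every pipeline knob.

Defaults reproduce the smallest benchmark profile of the embedder
(64-dimensional embeddings, learning rate 0.1, 4 negative samples, window
5, alpha 0.01 / beta 0.1 / gamma 0.1, stopping probability 0.15, restart
probability 0.7, 100 epochs) together with the standard screening
thresholds (c1 0.7, c2 0.6), SNF settings (K 20, t 20), 5 nearest
neighbours for pair construction, and a 100-tree class-weighted forest.

A single ``master_seed`` derives every stage seed by a fixed offset, so
stages are independently reproducible.  Unknown YAML keys are rejected —
no silent typo tolerance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .bine import BineHyperparams

__all__ = ["FusionConfig", "PairingConfig", "RFConfig", "EvalConfig",
           "RunConfig", "load_config", "config_from_dict", "dump_config"]

# fixed stage-seed offsets off the master seed
SEED_OFFSETS = {"bine": 1, "folds": 2, "rf": 3, "case_study": 4, "simulate": 5}


@dataclass(frozen=True)
class FusionConfig:
    c1: float = 0.7
    c2: float = 0.6
    K: int = 20
    t: int = 20
    alpha: float = 1.0
    entropy_reference: str = "max_possible"

    def __post_init__(self) -> None:
        if self.entropy_reference not in ("max_possible", "max_observed"):
            raise ValueError(f"invalid entropy_reference {self.entropy_reference!r}")
        if self.K < 1 or self.t < 1:
            raise ValueError("K and t must be >= 1")


@dataclass(frozen=True)
class PairingConfig:
    k_near: int = 5
    neighbor_mix: str = "as_printed"
    masking: str = "mask_test_edges"

    def __post_init__(self) -> None:
        if self.neighbor_mix not in ("as_printed", "neighbor_embeddings"):
            raise ValueError(f"invalid neighbor_mix {self.neighbor_mix!r}")
        if self.masking not in ("mask_test_edges", "transductive"):
            raise ValueError(f"invalid masking {self.masking!r}")
        if self.k_near < 1:
            raise ValueError("k_near must be >= 1")


@dataclass(frozen=True)
class RFConfig:
    n_estimators: int = 100
    criterion: str = "gini"
    class_weight: str = "balanced"
    min_samples_leaf: int = 1

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")


@dataclass(frozen=True)
class EvalConfig:
    task: str = "SD"
    folds: int = 10
    case_groups: int = 10
    top_k: int = 5

    def __post_init__(self) -> None:
        if self.task not in ("SD", "ST"):
            raise ValueError(f"invalid task {self.task!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass(frozen=True)
class RunConfig:
    bine: BineHyperparams = field(default_factory=BineHyperparams)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    pairing: PairingConfig = field(default_factory=PairingConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    master_seed: int = 0

    def stage_seed(self, stage: str) -> int:
        return (self.master_seed + SEED_OFFSETS[stage]) % (2**31)

    @property
    def honest_cv(self) -> bool:
        return self.pairing.masking == "mask_test_edges"


_SECTIONS = {
    "bine": BineHyperparams,
    "fusion": FusionConfig,
    "pairing": PairingConfig,
    "rf": RFConfig,
    "eval": EvalConfig,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in section {section!r}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid value in section {section!r}: {exc}") from exc


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config; unspecified fields take the documented defaults."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a YAML mapping")
    if overrides:
        for sect, vals in overrides.items():
            if isinstance(vals, dict):
                data.setdefault(sect, {})
                data[sect].update(vals)
            else:
                data[sect] = vals
    return config_from_dict(data)


def config_from_dict(data: dict) -> RunConfig:
    unknown = set(data) - set(_SECTIONS) - {"master_seed"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s) {sorted(unknown)}")
    sections = {
        name: _build_section(cls, data.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    master_seed = int(data.get("master_seed", 0))
    return RunConfig(master_seed=master_seed, **sections)


def dump_config(config: RunConfig) -> str:
    """Serialise a config to YAML; ``load(dump(x))`` is semantically x."""
    data = {
        name: dataclasses.asdict(getattr(config, name)) for name in _SECTIONS
    }
    data["master_seed"] = config.master_seed
    return yaml.safe_dump(data, sort_keys=True)
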