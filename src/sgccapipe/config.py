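"""Pipeline configuration: one YAML file as the single source of truth.

Every stochastic stage must carry an explicit seed — a config with a missing
seed is rejected, so a run is fully determined by its config file. Unknown
keys are errors (no silent typos).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    output_dir: str
    simulate: dict | None = None  # SyntheticSpec-like parameters, or None
    dataset: dict | None = None  # manifest: view name -> path, covariates, section_map
    split: dict = field(default_factory=dict)
    design: str | list = "uniform"
    scheme: str = "centroid"
    tuning: dict = field(default_factory=dict)
    components: dict = field(default_factory=dict)
    stability: dict = field(default_factory=dict)
    inference: dict = field(default_factory=dict)
    verbosity: int = 1

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=True))


_SCHEMA = {
    "output_dir": None,
    "simulate": {
        "n_participants", "n_true_components", "support_fraction", "loading_scale",
        "noise_sd", "seed", "n_sites", "confound_amplitude",
    },
    "dataset": {"views", "covariates", "section_map"},
    "split": {"fraction", "seed"},
    "design": None,
    "scheme": None,
    "tuning": {"grid", "n_perm", "n_components", "seed"},
    "components": {"k_max", "epsilon", "override"},
    "stability": {"n_subsamples", "fraction", "threshold", "seed", "skip_views"},
    "inference": {"n_perm", "n_boot", "alpha_coef", "fdr_alpha", "seed"},
    "verbosity": None,
}

_DEFAULTS = {
    "split": {"fraction": 0.7},
    "tuning": {"grid": [round(0.1 * i, 10) for i in range(1, 11)], "n_perm": 200, "n_components": 1},
    "components": {"k_max": 10, "epsilon": 0.01, "override": None},
    "stability": {"n_subsamples": 200, "fraction": 0.5, "threshold": 0.9, "skip_views": []},
    "inference": {"n_perm": 200, "n_boot": 1000, "alpha_coef": 0.008, "fdr_alpha": 0.05},
}

_SEEDED_SECTIONS = ["split", "tuning", "stability", "inference"]


def _check_keys(section: str, obj: dict, allowed: set[str]) -> None:
    unknown = set(obj) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {section!r}: {sorted(unknown)}")


def _require_range(value, lo, hi, path, inclusive_hi=False):
    ok = lo < value <= hi if inclusive_hi else lo < value < hi
    if not ok:
        raise ConfigError(f"{path} = {value} out of range")


def normalize_config(raw: dict) -> PipelineConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    _check_keys("<root>", raw, set(_SCHEMA))
    if "output_dir" not in raw:
        raise ConfigError("missing required key 'output_dir'")
    for section, allowed in _SCHEMA.items():
        if allowed is not None and section in raw and raw[section] is not None:
            if not isinstance(raw[section], dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            _check_keys(section, raw[section], allowed)
    merged = {}
    for section, defaults in _DEFAULTS.items():
        merged[section] = {**defaults, **(raw.get(section) or {})}
    cfg = PipelineConfig(
        output_dir=str(raw["output_dir"]),
        simulate=raw.get("simulate"),
        dataset=raw.get("dataset"),
        split=merged["split"],
        design=raw.get("design", "uniform"),
        scheme=raw.get("scheme", "centroid"),
        tuning=merged["tuning"],
        components=merged["components"],
        stability=merged["stability"],
        inference=merged["inference"],
        verbosity=int(raw.get("verbosity", 1)),
    )
    if cfg.simulate is None and cfg.dataset is None:
        raise ConfigError("config needs either 'simulate' or 'dataset'")
    for section in _SEEDED_SECTIONS:
        if getattr(cfg, section).get("seed") is None:
            raise ConfigError(f"missing seed: {section}.seed (every stochastic stage needs one)")
    if cfg.simulate is not None and cfg.simulate.get("seed") is None:
        raise ConfigError("missing seed: simulate.seed")
    _require_range(float(cfg.split["fraction"]), 0.0, 1.0, "split.fraction")
    _require_range(float(cfg.stability["fraction"]), 0.0, 1.0, "stability.fraction", inclusive_hi=True)
    if not 0 <= float(cfg.stability["threshold"]) <= 1:
        raise ConfigError(f"stability.threshold = {cfg.stability['threshold']} out of range")
    for lam in cfg.tuning["grid"]:
        _require_range(float(lam), 0.0, 1.0, "tuning.grid", inclusive_hi=True)
    if cfg.scheme not in ("horst", "centroid", "factorial"):
        raise ConfigError(f"scheme = {cfg.scheme!r} not one of horst/centroid/factorial")
    _require_range(float(cfg.inference["alpha_coef"]), 0.0, 1.0, "inference.alpha_coef")
    _require_range(float(cfg.inference["fdr_alpha"]), 0.0, 1.0, "inference.fdr_alpha")
    return cfg


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, default and cross-check a YAML config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    cfg = normalize_config(raw)
    return cfg
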