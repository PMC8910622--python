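"""Pipeline configuration: one YAML-serialisable object holding every tunable
parameter, with dotted-path overrides for the CLI's ``--set key=value``.

Defaults are the benchmark study's stated parameters (0.5–45 Hz FIR filter,
NFFT = epoch length, SampEn m=2 r=0.2·SD, NSI fraction 0.15, screening
threshold 0.02, 20% test split, 5-fold CV).
"""

from __future__ import annotations

import copy
from dataclasses import asdict, dataclass, field

import yaml


def _default_filter() -> dict:
    return {"low_hz": 0.5, "high_hz": 45.0, "n_taps": 401, "window": "hamming"}


@dataclass
class PipelineConfig:
    fs: float = 100.0
    epoch_s: float = 30.0
    filter: dict = field(default_factory=_default_filter)
    nfft: int | None = None  # None: use the epoch length (no zero padding)
    sampen_m: int = 2
    sampen_r: float = 0.2
    nsi_fraction: float = 0.15
    selection_threshold: float = 0.02
    selection_trees: int = 100
    test_frac: float = 0.2
    k_folds: int = 5
    seed: int = 0
    models: dict = field(default_factory=dict)  # kind -> hyperparameter overrides

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**copy.deepcopy(d))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def with_overrides(self, overrides: list[str]) -> "PipelineConfig":
        """Apply ``key=value`` / ``a.b=value`` overrides (YAML-parsed values)."""
        d = self.to_dict()
        for item in overrides:
            if "=" not in item:
                raise ValueError(f"override {item!r} is not of the form key=value")
            key, raw = item.split("=", 1)
            value = yaml.safe_load(raw)
            node = d
            parts = key.strip().split(".")
            for part in parts[:-1]:
                node = node.setdefault(part, {})
            node[parts[-1]] = value
        return self.from_dict(d)

    @classmethod
    def load(cls, path=None, overrides: list[str] | None = None) -> "PipelineConfig":
        cfg = cls.from_yaml(path) if path else cls()
        if overrides:
            cfg = cfg.with_overrides(list(overrides))
        return cfg
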