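"""Run configuration: YAML/JSON round-trippable, fail-fast on unknown keys."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run.

    Defaults mirror the analysis design: 20 %/40 % tract-map threshold
    fractions, LOOCV with accuracy as the selection statistic, and
    desk-scale permutation/bootstrap counts (the study-scale value for
    both is 10,000).
    """
    out_dir: str = "results"
    seed: int = 0
    n_voxels: int = 940
    hemisphere: str = "right"
    n_pos: int = 19
    n_neg: int = 17
    effect_metric: str = "MD"
    amplitude_sd_ratio: float = 3.0
    metric: str = "MD"
    family: str = "svm"
    kernel: str = "rbf"
    threshold_fraction_uf: float = 0.20
    threshold_fraction_slf: float = 0.40
    statistic: str = "accuracy"
    n_perm: int = 500
    n_boot: int = 500
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    nested: bool = False
    verbosity: int = 1

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") \
                else json.load(fh)
        data = data or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yml", ".yaml"):
                yaml.safe_dump(asdict(self), fh, sort_keys=True)
            else:
                json.dump(asdict(self), fh, indent=2, sort_keys=True)

    def as_dict(self) -> dict:
        return asdict(self)
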