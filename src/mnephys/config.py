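"""Run configuration: a structured YAML file mirroring the cohort spec,
protocol set, extraction constants and statistics parameters."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cohort import (CohortSpec, GroupSpec, ParamDist, mild_shift,
                     severe_shift, sham_distributions)

__all__ = ["RunConfig", "load_config", "dump_config", "config_hash"]

_DEFAULT_N = {"sham": 9, "HI_unaffected": 12, "HI_mild": 10, "HI_severe": 8}


@dataclass
class RunConfig:
    """Everything a pipeline run needs, resolvable at run start."""
    seed: int = 0
    output_dir: str = "mnephys_out"
    sweep_dialect: str = "text"          # text | hdf5
    n_per_group: dict = field(default_factory=lambda: dict(_DEFAULT_N))
    dist_overrides: dict = field(default_factory=dict)  # group->field->dist
    dt_ms: float = 0.025
    # extraction constants (paper-gap defaults, auditable here)
    leak_window_offset: tuple = (5.0, 25.0)   # mV above holding
    pic_onset_base_pA: float = 5.0
    pic_onset_noise_mult: float = 3.0
    # statistics
    alpha: float = 0.05
    adjust: str = "holm"
    reference: str = "sham"

    def __post_init__(self) -> None:
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")
        if self.sweep_dialect not in ("text", "hdf5"):
            raise ValueError(f"unknown sweep dialect {self.sweep_dialect!r}")

    def cohort_spec(self) -> CohortSpec:
        base = {
            "sham": sham_distributions(),
            "HI_unaffected": sham_distributions(),
            "HI_mild": {**sham_distributions(), **mild_shift()},
            "HI_severe": {**sham_distributions(), **severe_shift()},
        }
        groups = {}
        for g, n in self.n_per_group.items():
            dists = dict(base.get(g, sham_distributions()))
            for fname, dd in self.dist_overrides.get(g, {}).items():
                dists[fname] = ParamDist(**dd)
            groups[g] = GroupSpec(n=int(n), distributions=dists)
        return CohortSpec(groups=groups, seed=self.seed)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from YAML; ``None`` gives the packaged defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "leak_window_offset" in raw:
        raw["leak_window_offset"] = tuple(raw["leak_window_offset"])
    return RunConfig(**raw)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    d = asdict(cfg)
    d["leak_window_offset"] = list(cfg.leak_window_offset)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    d = asdict(cfg)
    d["leak_window_offset"] = list(cfg.leak_window_offset)
    blob = yaml.safe_dump(d, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
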