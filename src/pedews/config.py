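"""Single declarative configuration for the whole pipeline.

One ``PipelineConfig`` carries every scalar the stages need: reference
directory, window geometry, outcome rules (lactate threshold, cv-rise
baseline mode), search settings, split fractions, the recall set-point and
the number of repeats. It round-trips through YAML and exposes a stable
fingerprint used for idempotent stage skipping.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .models import SearchConfig
from .synthetic import CohortSpec
from .windows import WindowSpec

__all__ = ["PipelineConfig", "default_config"]


@dataclass(frozen=True)
class PipelineConfig:
    reference_dir: str | None = None   # None -> packaged defaults
    variable_map: str | None = None
    imputation_policy: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    window: WindowSpec = field(default_factory=WindowSpec)
    search: SearchConfig = field(default_factory=SearchConfig)
    split_fractions: tuple[tuple[str, float], ...] = (("train", 0.85), ("test", 0.15))
    lactate_threshold_mmol_l: float = 2.0
    cv_rise_baseline: str = "lookback_max"  # or "at_anchor"
    age_normalise: bool = True
    recall_setpoint: float = 0.9
    repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.split_fractions)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"split fractions sum to {total}, expected 1")
        for name in ("reference_dir", "variable_map", "imputation_policy"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")

    @property
    def fractions(self) -> dict[str, float]:
        return dict(self.split_fractions)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["age_dist"] = [list(b) for b in d["cohort"]["age_dist"]]
        d["split_fractions"] = [list(x) for x in d["split_fractions"]]
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "cohort" in raw:
            c = dict(raw["cohort"])
            if "age_dist" in c:
                c["age_dist"] = tuple(tuple(b) for b in c["age_dist"])
            raw["cohort"] = CohortSpec(**c)
        if "window" in raw:
            raw["window"] = WindowSpec(**raw["window"])
        if "search" in raw:
            s = dict(raw["search"])
            if isinstance(s.get("space"), dict):
                s["space"] = {k: tuple(v) for k, v in s["space"].items()}
            raw["search"] = SearchConfig(**s)
        if "split_fractions" in raw:
            raw["split_fractions"] = tuple((n, float(f)) for n, f in raw["split_fractions"])
        return cls(**raw)

    def fingerprint(self) -> str:
        return hashlib.md5(yaml.safe_dump(self.to_dict(), sort_keys=True).encode()).hexdigest()


def default_config(**overrides) -> PipelineConfig:
    """Packaged defaults; keyword overrides replace top-level fields."""
    return dataclasses.replace(PipelineConfig(), **overrides)
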