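"""Run configuration: thresholds, paths, channel map, seeds.

Defaults mirror the screen's analysis settings: cytotoxicity cut at 25%
of vehicle cell counts, ANOVA p < 0.05 with a one-unit (2-fold on a
log2-like scale) mean-shift filter, benchmark response factor 1.349 at
95% confidence, 250 optimizer iterations.  The config round-trips
losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .profiles import DEFAULT_CHANNEL_MAP


@dataclass
class RunConfig:
    # paths
    workdir: str = "."
    # channel token -> stain
    channel_map: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    # preprocessing
    cytotox_threshold: float = 0.25
    glog_offset: float | None = 1.0  # None disables the transform
    # prefilter
    anova_p_cut: float = 0.05
    fold_change_cut: float = 1.0
    # dose-response
    bmr_factor: float = 1.349
    confidence_level: float = 0.95
    max_iterations: int = 250
    n_starts: int = 8
    poly_degrees: tuple = (1, 2)
    compute_bmcl: bool = True
    # overlap
    overlap_universe: str = "stratum"  # or "global"
    sign_aware_overlap: bool = False
    # synthetic-data defaults
    sim_n_features: int = 500
    sim_n_chemicals: int = 2
    sim_cells_per_well: float = 500.0
    sim_replicates: int = 6
    # seeds
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.cytotox_threshold < 1:
            raise ValueError("cytotox_threshold must be in (0, 1)")
        if self.glog_offset is not None and self.glog_offset <= 0:
            raise ValueError("glog_offset must be positive or None")
        if not 0 < self.anova_p_cut < 1:
            raise ValueError("anova_p_cut must be in (0, 1)")
        if self.fold_change_cut < 0:
            raise ValueError("fold_change_cut must be non-negative")
        if self.bmr_factor <= 0:
            raise ValueError("bmr_factor must be positive")
        if not 0.5 < self.confidence_level < 1:
            raise ValueError("confidence_level must be in (0.5, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.overlap_universe not in ("stratum", "global"):
            raise ValueError("overlap_universe must be 'stratum' or 'global'")

    # -- YAML round trip -------------------------------------------------

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = dataclasses.asdict(self)
        data["poly_degrees"] = list(self.poly_degrees)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "poly_degrees" in data:
            data["poly_degrees"] = tuple(data["poly_degrees"])
        cfg = cls(**data)
        cfg.validate()
        return cfg
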