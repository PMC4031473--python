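"""Pipeline configuration: the analysis constants, with study defaults."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from typing import Optional

import yaml

from .core import ConfigurationError


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline.

    Defaults are the study conditions: a 3 kb TSS window for target
    assignment, fold-enrichment > 10 peak filtering, a 6 kb (±3 kb)
    heatmap window, 600 bp summit-centred motif windows, adjusted
    p < 0.001 for differential expression, a 100-gene expression
    smoothing window, and top-1000 active/repressive target selection.
    """

    tss_window: int = 3000           # bp around TSS for target assignment
    fold_threshold: float = 10.0     # strict > filter on fold enrichment
    heatmap_halfwindow: int = 3000   # bp each side of the anchor
    profile_bins: int = 120          # 50-bp bins over the 6 kb window
    motif_window: int = 600          # bp, summit centred
    de_alpha: float = 0.001          # significance cutoff for DE calls
    de_use_adjusted: bool = True     # threshold BH-adjusted p (vs raw p)
    smooth_window: int = 100         # genes per sliding-average window
    top_n: int = 1000                # active/repressive genes to select
    rp_decay_distance: int = 100_000  # bp, regulatory-potential decay scale
    rp_horizon: int = 100_000        # bp, peaks beyond this contribute 0
    expression_threshold: float = 6.0  # mean control log2 intensity
    min_overlap_bp: int = 1          # bp overlap defining co-occupancy
    ks_alpha: float = 0.01           # KS threshold for direction labels
    use_summit_distance: bool = True  # summit (vs whole-peak edge) distances
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tss_window", "heatmap_halfwindow", "profile_bins",
                     "motif_window", "smooth_window", "top_n",
                     "rp_decay_distance", "rp_horizon", "min_overlap_bp"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 < self.de_alpha < 1:
            raise ConfigurationError("de_alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
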