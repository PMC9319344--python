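"""Pipeline configuration with defaults mirroring the published analysis."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    """All stage thresholds in one place; overrides are logged by the runner.

    Defaults reproduce the published settings: adjusted-p cutoff 0.01 with a
    |corrected log2FC| grid 1.0–2.0 in steps of 0.1; STRING combined-score
    threshold 0.4; RRA hub filter p < 0.01; MCODE cluster-score filter ≥ 7
    (degree cutoff 2, node score cutoff 0.2, k-core 2, haircut, max depth
    100); consensus co-expression with soft power 7, minimum module size 30,
    merge height 0.25, scale-free R² ≥ 0.77, median connectivity < 30, and a
    >20-sample inclusion rule; biofluid screens at α = 0.05; LASSO-Cox with
    10 folds × 100 iterations and a 75% selection-frequency rule; panel CV
    5-fold × 10 repeats per dataset and a single 10-fold pass on the merged
    matrix.
    """

    # differential expression
    de_p_adj_max: float = 0.01
    fc_grid_start: float = 1.0
    fc_grid_stop: float = 2.0
    fc_grid_step: float = 0.1
    # PPI network
    string_min_score: float = 0.4
    rra_p_max: float = 0.01
    mcode_score_min: float = 7.0
    mcode_degree_cutoff: int = 2
    mcode_node_score_cutoff: float = 0.2
    mcode_k_core: int = 2
    mcode_haircut: bool = True
    mcode_max_depth: int = 100
    # consensus co-expression
    wgcna_power: int = 7
    wgcna_min_module_size: int = 30
    wgcna_merge_height: float = 0.25
    wgcna_r2_min: float = 0.77
    wgcna_median_k_max: float = 30.0
    wgcna_min_samples: int = 20
    module_trait_p_max: float = 0.01
    # screens
    fluid_alpha: float = 0.05
    # survival
    lasso_folds: int = 10
    lasso_iters: int = 100
    lasso_freq_min: float = 0.75
    cox_p_max: float = 0.05
    roc_horizons: tuple[float, ...] = (1.0, 3.0, 5.0, 10.0)
    time_unit: str = "years"
    # diagnostics panel
    panel_folds: int = 5
    panel_repeats: int = 10
    merged_panel_folds: int = 10
    # misc
    seed: int = 0
    wgcna_exclude_datasets: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("roc_horizons", "wgcna_exclude_datasets"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @property
    def fc_grid(self) -> tuple[float, ...]:
        import numpy as np

        return tuple(
            np.round(
                np.arange(
                    self.fc_grid_start,
                    self.fc_grid_stop + self.fc_grid_step / 2,
                    self.fc_grid_step,
                ),
                6,
            )
        )


PUBLISHED_DEFAULTS = {
    "de_p_adj_max": 0.01,
    "fc_grid_start": 1.0,
    "fc_grid_stop": 2.0,
    "fc_grid_step": 0.1,
    "string_min_score": 0.4,
    "rra_p_max": 0.01,
    "mcode_score_min": 7.0,
    "mcode_degree_cutoff": 2,
    "mcode_node_score_cutoff": 0.2,
    "mcode_k_core": 2,
    "mcode_haircut": True,
    "mcode_max_depth": 100,
    "wgcna_power": 7,
    "wgcna_min_module_size": 30,
    "wgcna_merge_height": 0.25,
    "wgcna_r2_min": 0.77,
    "wgcna_median_k_max": 30.0,
    "wgcna_min_samples": 20,
    "fluid_alpha": 0.05,
    "lasso_folds": 10,
    "lasso_iters": 100,
    "lasso_freq_min": 0.75,
    "panel_folds": 5,
    "panel_repeats": 10,
    "merged_panel_folds": 10,
}


def self_test() -> None:
    """Assert every numeric default matches the published setting."""
    cfg = PipelineConfig().to_dict()
    for key, value in PUBLISHED_DEFAULTS.items():
        if cfg[key] != value:
            raise AssertionError(
                f"config default {key}={cfg[key]} differs from published {value}"
            )
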