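"""Pipeline configuration: thresholds, trait contrasts, YAML loading.

Every decision threshold used by the stages lives here with its study
default, so a config file can override any of them and overrides are visible
in the run manifest.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: Trait contrast map. Categorical AD phenotypes enter the regressions as
#: binary contrasts: CERAD 1-2 (Definite/Probable AD pathology) vs 3-4;
#: Braak 3+ vs 0-2; clinical diagnosis MCI-or-AD vs NCI. Continuous traits
#: pass through unchanged.
DEFAULT_CONTRASTS: dict[str, dict] = {
    "cerad": {"kind": "le_threshold", "threshold": 2},
    "braak": {"kind": "ge_threshold", "threshold": 3},
    "clinical_dx": {"kind": "in_set", "levels": ["MCI", "AD"]},
}


def encode_trait(trait: str, values: pd.Series, contrasts: dict | None = None) -> np.ndarray:
    """Numeric encoding of a trait column per the contrast map."""
    cmap = DEFAULT_CONTRASTS if contrasts is None else contrasts
    rule = cmap.get(trait)
    if rule is None:
        return values.to_numpy(dtype=float)
    kind = rule["kind"]
    if kind == "le_threshold":
        out = (values.astype(float) <= rule["threshold"]).astype(float)
    elif kind == "ge_threshold":
        out = (values.astype(float) >= rule["threshold"]).astype(float)
    elif kind == "in_set":
        out = values.isin(rule["levels"]).astype(float)
    else:
        raise ValueError(f"unknown contrast kind {kind!r}")
    return out.to_numpy(dtype=float)


#: Pathological and cognitive traits analyzed by default.
DEFAULT_TRAITS = [
    "cerad",
    "braak",
    "neuritic_plaques",
    "diffuse_plaques",
    "amyloid_sqrt",
    "tangles_sqrt",
    "clinical_dx",
    "cog_decline",
]


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`popcellmeta.pipeline.run_pipeline`."""

    seed: int = 0
    out_dir: str = "popcellmeta_run"
    # synthetic cohort
    n_per_group: int = 30
    region_coverage: float = 1.0
    subclusters: list[str] = field(
        default_factory=lambda: [f"SC{i}" for i in range(8)]
    )
    total_nuclei: float = 5000.0
    concentration: float = 50.0
    planted_effects: list[dict] = field(default_factory=list)
    # analysis thresholds (study defaults)
    alpha: float = 0.05
    i2_max: float = 50.0
    corr_max: float = 0.75
    merge_min_genes: int = 4
    merge_lfc_min: float = 2.0
    consensus_splits: int = 5
    consensus_min_agree: int = 4
    qc_min_umis: int = 500
    qc_max_mito_pct: float = 5.0
    top_genes_n: int = 5
    top_genes_cpm_min: float = 10.0
    traits: list[str] = field(default_factory=lambda: list(DEFAULT_TRAITS))
    contrasts: dict = field(default_factory=lambda: dict(DEFAULT_CONTRASTS))
    weighted: bool = True
    hc: str = "HC3"
    truncate_hksj: bool = False
    # factor stage
    factor_k_grid: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    factor_n_cells: int = 400
    factor_n_genes: int = 150
    factor_k_true: int = 3
    # subgroup stage
    subgroup_k_min: int = 2
    subgroup_k_max: int = 8
    subgroup_region: str = "STG"
    # stage toggles
    run_factors: bool = True
    run_subgroups: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.i2_max <= 100:
            raise ValueError("i2_max must lie in [0, 100]")
        if not 0 < self.corr_max <= 1:
            raise ValueError("corr_max must lie in (0, 1]")
        if self.consensus_min_agree > self.consensus_splits:
            raise ValueError("consensus_min_agree cannot exceed consensus_splits")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config (defaults for missing keys) and apply overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(PipelineConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update(overrides)
    return PipelineConfig(**data)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
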