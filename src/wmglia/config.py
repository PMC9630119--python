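"""Validated pipeline configuration (YAML-backed, unknown keys rejected)."""
from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Block):
    n_per_group: int = Field(4, ge=1)
    cells_per_sample: int = Field(320, ge=1)
    n_genes: int = Field(1500, ge=50)
    marker_fold: float = Field(8.0, ge=1.0)
    platform: str = "smartseq2"


class QCConfig(_Block):
    # Smart-seq2 interval overrides, e.g. {reads: [20000, 4.0e6]}
    smartseq_thresholds: dict[str, tuple[float, float]] = Field(default_factory=dict)
    droplet_min_cells_per_gene: int = 3
    droplet_min_genes_per_cell: int = 200
    droplet_max_frac_mito: float = 0.10
    droplet_max_umi: int | None = None
    droplet_max_genes: int | None = None
    n_qc_violations: int = 12


class StatesConfig(_Block):
    tau: float = 0.5
    scale_factor: float = 1e4
    signatures: dict[str, list[str]] | None = None
    assign_order: list[str] = Field(
        default_factory=lambda: ["IRO", "ARO", "IRM", "T_NK"]
    )
    marker_fc_threshold: float = 1.0
    top_k: int = 50


class CompositionConfig(_Block):
    fdr: float = Field(0.4, gt=0, le=1)
    group_factor: str = "age_months"


class ProximityConfig(_Block):
    radius: float = Field(20.0, gt=0)
    n_null_draws: int = Field(100, ge=1)
    assoc_prob: float = Field(0.5, ge=0, le=1)
    displacement_sigma: float = Field(8.0, gt=0)
    n_mice: int = Field(4, ge=2)
    n_sections_per_mouse: int = Field(3, ge=1)
    window: tuple[float, float] = (600.0, 600.0)
    dapi_intensity: float = Field(0.001, gt=0)
    n_ref: int = Field(11, ge=1)
    n_target: int = Field(23, ge=1)


class PipelineConfig(_Block):
    """Full pipeline settings; every stage block has working defaults."""

    seed: int = 0
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    qc: QCConfig = Field(default_factory=QCConfig)
    states: StatesConfig = Field(default_factory=StatesConfig)
    composition: CompositionConfig = Field(default_factory=CompositionConfig)
    proximity: ProximityConfig = Field(default_factory=ProximityConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)
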