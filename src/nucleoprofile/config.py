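"""Schema-validated configuration for the analysis pipeline.

Every numeric threshold named in the module docstrings is a config key
here, so a YAML file can reproduce or re-tune a full run.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .profiles import ClassifierConfig

__all__ = ["AnalysisParams", "SimulationParams", "CellCycleParams", "PipelineConfig"]


class AnalysisParams(BaseModel):
    """Segmentation, detection and classification thresholds."""

    min_nucleus_px: int = Field(500, ge=1)
    nucleolus_percentile: float = Field(20.0, gt=0, lt=100)
    min_nucleolus_px: int = Field(50, ge=1)
    hc_fixed_threshold: float | None = Field(None, ge=0, le=255)
    hc_min_contrast: float = Field(30.0, ge=0)
    foci_k: float = Field(3.0, gt=0)
    foci_min_rise: float = Field(40.0, ge=0)
    min_focus_px: int = Field(3, ge=1)
    foci_fixed_threshold: float | None = Field(None, ge=0, le=255)
    # classifier thresholds (see ClassifierConfig for what each encodes)
    t3_cluster_fraction: float = Field(0.5, ge=0, le=1)
    ring_score_min: float = Field(0.5, ge=0, le=1)
    ring_focus_min: int = Field(4, ge=1)
    ring_intensity_min: float = Field(1.0, ge=0)
    t1_nucleolar_fraction: float = Field(0.9, ge=0, le=1)
    t2_nucleolar_fraction_max: float = Field(0.05, ge=0, le=1)
    light_nucleolus_ratio: float = Field(1.2, ge=0)
    n_sectors: int = Field(12, ge=4)
    annulus_width_factor: float = Field(0.15, gt=0)
    annulus_min_width_px: float = Field(3.0, gt=0)
    cluster_factor: float = Field(5.0, gt=0)

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(
            t3_cluster_fraction=self.t3_cluster_fraction,
            ring_score_min=self.ring_score_min,
            ring_focus_min=self.ring_focus_min,
            ring_intensity_min=self.ring_intensity_min,
            t1_nucleolar_fraction=self.t1_nucleolar_fraction,
            t2_nucleolar_fraction_max=self.t2_nucleolar_fraction_max,
            light_nucleolus_ratio=self.light_nucleolus_ratio,
            n_sectors=self.n_sectors,
            annulus_width_factor=self.annulus_width_factor,
            annulus_min_width_px=self.annulus_min_width_px,
            cluster_factor=self.cluster_factor,
        )


class SimulationParams(BaseModel):
    """Synthetic population to generate before analysis."""

    conditions: dict[str, int] = Field(default_factory=lambda: {"CONTROL": 30})
    noise_sd: float = Field(0.0, ge=0)
    labeled_fraction: dict[str, float] | None = None

    @field_validator("conditions")
    @classmethod
    def _counts_nonneg(cls, v: dict[str, int]) -> dict[str, int]:
        if any(c < 0 for c in v.values()):
            raise ValueError("condition counts must be non-negative")
        return v


class CellCycleParams(BaseModel):
    """DNA-content simulation / fitting settings."""

    n_events: int = Field(10000, ge=100)
    g1_mean: float = Field(100.0, gt=0)
    g2_ratio: float = Field(2.0, gt=1, le=2.5)
    cv: float = Field(0.05, gt=0)
    s_fraction: dict[str, float] = Field(
        default_factory=lambda: {"CONTROL": 0.2617, "HU": 0.4106, "PCC": 0.3851}
    )
    g2m_fraction: dict[str, float] = Field(
        default_factory=lambda: {"CONTROL": 0.0818, "HU": 0.024, "PCC": 0.1125}
    )


class PipelineConfig(BaseModel):
    """Top-level run configuration (YAML-serializable)."""

    simulate: SimulationParams | None = SimulationParams()
    images_dir: str | None = None
    analysis: AnalysisParams = AnalysisParams()
    cellcycle: CellCycleParams | None = None
    heatmap_count: int = Field(3, ge=0)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
        return path
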