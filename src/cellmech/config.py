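"""Run configuration schema (validated before any stage executes)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError


class PillarGeometryConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    pitch_um: float  # required: no safe default for an unknown array
    diameter_um: float = 0.9
    height_um: float = 1.0
    youngs_modulus_pa: float = 2e6
    stiffness_override_nn_per_um: float | None = None


class PillarSceneConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    image_shape: tuple[int, int] = (192, 192)
    pixel_size_um: float = 0.2
    n_frames: int = 5
    photon_level: float = 500.0
    background: float = 20.0
    psf_sigma_px: float = 1.5
    read_noise_sd: float = 2.0
    drift_per_frame_um: tuple[float, float] = (0.02, 0.0)
    cell_radius_um: float = 8.0
    n_deflected: int = 10
    deflection_range_um: tuple[float, float] = (0.1, 0.4)


class TfmStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    geometry: PillarGeometryConfig
    scene: PillarSceneConfig = PillarSceneConfig()
    stack: Path | None = None  # analyze an existing stack instead of simulating
    mask: Path | None = None
    margin_um: float = 2.0
    lattice: Literal["square", "hexagonal"] = "square"


class GpSceneConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    image_shape: tuple[int, int] = (256, 256)
    ordered_gp: float = 0.6
    fluid_gp: float = -0.4
    domain_radius_px: float = 60.0
    total_intensity: float = 400.0
    np_level: float = 300.0
    shot_noise: bool = True


class GpStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    scene: GpSceneConfig = GpSceneConfig()
    n_bins: int = 100
    intensity_threshold: float | None = None
    gp_threshold: float = 0.3
    np_threshold: float = 100.0
    ch420: Path | None = None
    ch473: Path | None = None
    np_channel: Path | None = None


class TracksStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_cells: int = 20
    sampling_interval_min: float = 5.0
    duration_h: float = 6.0
    speed_mean: float = 0.5
    speed_sd: float = 0.15
    turning_sd_rad: float = 0.4
    tracks: Path | None = None  # analyze an existing track table


class OmicsStageConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_genes: int = 500
    n_metabolites: int = 40
    n_planted_genes: int = 5
    planted_gene_fc: float = 4.0
    n_planted_metabolites: int = 5
    planted_metabolite_change: float = 0.3
    noise_sd: float = 0.0
    gene_cutoff: float = 3.0
    metabolite_cutoff: float = 0.20
    genes: Path | None = None
    metabolites: Path | None = None


class RunConfig(BaseModel):
    """Full run description; every stage block is optional but must be
    present for each requested stage."""

    model_config = ConfigDict(extra="forbid")

    stages: list[Literal["tfm", "gp", "tracks", "omics"]]
    seed: int = 0
    outdir: Path = Path("cellmech_run")
    tfm: TfmStageConfig | None = None
    gp: GpStageConfig | None = None
    tracks: TracksStageConfig = Field(default_factory=TracksStageConfig)
    omics: OmicsStageConfig = Field(default_factory=OmicsStageConfig)


def load_run_config(raw: dict) -> RunConfig:
    """Validate a raw config mapping; schema errors become ConfigError."""
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid run configuration:\n{exc}") from exc
    for stage in cfg.stages:
        if getattr(cfg, stage) is None:
            raise ConfigError(f"stage {stage!r} requested but its config block is missing")
    return cfg
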