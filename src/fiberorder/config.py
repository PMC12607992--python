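"""Run configuration: schema-validated nested config with seed fan-out.

A single global seed is fanned out to stage seeds (generate / train /
pipeline) through a documented hash — blake2s of ``"{seed}:{stage}"``,
truncated to 31 bits — so each stage is reproducible on its own.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "stage_seed", "load_run_config"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeneratorSection(_Strict):
    image_size: int = 256
    n_fibers: tuple[int, int] = (1200, 2400)
    fiber_length: tuple[float, float] = (32.0, 96.0)
    fiber_thickness: tuple[float, float] = (1.0, 1.5)
    fiber_intensity: tuple[float, float] = (0.6, 1.0)
    background_level: float = 0.1
    noise_sd: float = 0.05
    blur_sigma: float = 0.7
    aligned_jitter: float = 0.0
    angle_law: str = "mixture"


class ModelSection(_Strict):
    input_size: int = 128


class TrainingSection(_Strict):
    epochs: int = 50
    batch_size: int = 16
    learning_rate: float = 1e-3
    augment: bool = True


class PipelineSection(_Strict):
    patch_size: int = 256
    stride: int = 128
    mask_rects: list[tuple[int, int, int, int]] = Field(default_factory=list)


class RunConfig(_Strict):
    """Top-level configuration mirrored by the CLI flags."""

    generator: GeneratorSection = Field(default_factory=GeneratorSection)
    model: ModelSection = Field(default_factory=ModelSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    pipeline: PipelineSection = Field(default_factory=PipelineSection)
    seed: int = 0
    out_dir: str = "fiberorder_out"
    log_level: str = "INFO"

    def generator_config(self):
        from .synth import GeneratorConfig

        g = self.generator
        return GeneratorConfig(
            image_size=g.image_size,
            n_fibers=g.n_fibers,
            fiber_length=g.fiber_length,
            fiber_thickness=g.fiber_thickness,
            fiber_intensity=g.fiber_intensity,
            background_level=g.background_level,
            noise_sd=g.noise_sd,
            blur_sigma=g.blur_sigma,
            aligned_jitter=g.aligned_jitter,
            angle_law=g.angle_law,
            seed=stage_seed(self.seed, "generate"),
        )


def load_run_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run config; defaults when ``path`` is None."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)
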