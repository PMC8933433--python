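"""Run configuration: validated schema with the standard parameter set.

All numeric defaults are the standard operating point of the model
(omega = 1.5, gamma = rho = 0.5, tau = pi/3, storage 40 s at dt = 0.1,
retrieval 15 s — 30 s for the semantic task — at dt = 0.01, sigma = 0.02,
display threshold 0.002).  Configs are YAML or JSON files; unknown keys
are rejected so typos surface as schema errors, and the JSON schema is
available from :func:`config_schema`.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import List, Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .dynamics import ModelParams

__all__ = ["RunConfig", "load_config", "config_schema", "config_hash"]


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    omega: float = Field(1.5, gt=0)
    gamma: float = Field(0.5, ge=0)
    rho: float = Field(0.5, ge=0)
    tau: float = Field(math.pi / 3.0, gt=0)
    storage_T: float = Field(40.0, gt=0)
    storage_dt: float = Field(0.1, gt=0)
    retrieval_T: float = Field(15.0, gt=0)
    retrieval_dt: float = Field(0.01, gt=0)

    @model_validator(mode="after")
    def _consistent(self):
        if self.tau >= self.storage_T:
            raise ValueError("tau must be smaller than storage_T")
        if self.tau < self.storage_dt:
            raise ValueError("tau must be at least one storage step")
        return self

    def storage_params(self) -> ModelParams:
        return ModelParams(omega=self.omega, gamma=self.gamma, rho=self.rho,
                           tau=self.tau, dt=self.storage_dt, T=self.storage_T)


class EncodingSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sigma: float = Field(0.02, gt=0)
    sigma_display: float = Field(0.002, gt=0)
    height: int = Field(16, ge=4)
    width: int = Field(16, ge=4)
    n_images: int = Field(5, ge=1)
    style: Literal["blobs", "shapes", "noise"] = "blobs"
    image_dir: Optional[str] = None      # read PNGs instead of synthesizing


class CueSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mode: Literal["exact", "noisy", "occluded", "irrelevant"] = "noisy"
    alpha: float = Field(0.25, ge=0, le=1)
    beta: float = Field(0.2, ge=0, le=1)
    # semantic cues as "word:role" strings, e.g. ["John:S", "Mary:O"]
    components: List[str] = Field(default_factory=list)
    occlusion_box: Optional[List[int]] = None


class CapacitySection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    D: int = Field(200, ge=1)
    K: int = Field(20, ge=1)
    n_values: List[int] = Field(default_factory=lambda: [2, 4, 8, 16])
    reps: int = Field(5, ge=1)


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    task: Literal["image", "capacity", "semantic"] = "image"
    model: ModelSection = Field(default_factory=ModelSection)
    encoding: EncodingSection = Field(default_factory=EncodingSection)
    cue: CueSection = Field(default_factory=CueSection)
    capacity: CapacitySection = Field(default_factory=CapacitySection)
    seed: int = 0
    outdir: str = "runs"

    @model_validator(mode="after")
    def _task_defaults(self):
        if self.task == "semantic" and "retrieval_T" not in self.model.model_fields_set:
            self.model.retrieval_T = 30.0
        return self


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON config file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)


def config_schema() -> dict:
    """The published JSON schema all configs validate against."""
    return RunConfig.model_json_schema()


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of a config for provenance records."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
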