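"""Schema-validated experiment configuration.

A single YAML file (or nested dict) describes an end-to-end experiment: data
generation, network architecture, training, unlearning, and evaluation.
Every field has a typed default; unknown keys are rejected. One top-level
``seed`` fans out deterministically to per-stage seeds (SHA-256 of the stage
name and the run seed) so stages can be rerun in isolation.
"""

from __future__ import annotations

import hashlib
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataSection(_Section):
    kind: Literal["image", "timeseries", "separable"] = "separable"
    n_samples: int = Field(150, ge=4)
    n_classes: int = Field(2, ge=2)
    noise_sd: float = Field(0.05, ge=0)
    n_channels: int = Field(10, ge=1)  # per class for "separable"; total for "timeseries"
    n_timesteps: int = Field(64, ge=2)  # timeseries kind
    split: tuple[float, float, float] = (0.7, 0.15, 0.15)


class NetworkSection(_Section):
    hidden_sizes: tuple[int, ...] = (40,)
    connectivity_prob: float = Field(0.5, gt=0, le=1)
    neuron_kind: Literal["lif", "izhikevich"] = "lif"
    tau_m: float = Field(10.0, gt=0)
    v_thresh: float = 0.5
    v_reset: float = 0.0
    weight_init_std: float = Field(0.05, gt=0)


class TrainingSection(_Section):
    epochs: int = Field(1, ge=0)
    batch_size: int = Field(20, ge=1)
    learning_rate: float = Field(0.01, ge=0)
    dropout_rate: float = Field(0.2, ge=0, lt=1)
    a_pos: float = Field(0.1, ge=0)
    a_neg: float = Field(0.05, ge=0)
    tau_pos: float = Field(20.0, gt=0)
    tau_neg: float = Field(20.0, gt=0)
    pairing: Literal["nearest", "all"] = "nearest"
    duration_ms: float = Field(200.0, gt=0)
    dt_ms: float = Field(1.0, gt=0)
    max_rate_hz: float = Field(100.0, gt=0)
    teacher_current: float = 1.0


class UnlearningSection(_Section):
    mode: Literal["class", "sample"] = "class"
    target: Optional[int] = None  # class mode; None = random class
    fraction: float = Field(0.1, gt=0, le=1)  # sample mode
    alpha: float = Field(1.0, ge=0, le=1)
    corr_percentile: float = Field(75.0, ge=0, le=100)
    dw_percentile: float = Field(75.0, ge=0, le=100)
    prune_percentile: float = Field(50.0, ge=0, le=100)
    gamma: float = -0.002
    beta: float = 0.01
    max_iterations: int = Field(5, ge=1)
    prune_scope: Literal["selection", "global"] = "selection"
    prune_criterion: Literal["magnitude", "nonpositive"] = "magnitude"
    retrain_epochs: int = Field(2, ge=0)


class EvaluationSection(_Section):
    run_mia: bool = True


class ExperimentConfig(_Section):
    """Top-level experiment description; see the section models for fields."""

    seed: int = 0
    data: DataSection = Field(default_factory=DataSection)
    network: NetworkSection = Field(default_factory=NetworkSection)
    training: TrainingSection = Field(default_factory=TrainingSection)
    unlearning: UnlearningSection = Field(default_factory=UnlearningSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ExperimentConfig(**raw)


def stage_seed(run_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the run seed (< 2^31)."""
    h = hashlib.sha256(f"{stage}:{run_seed}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
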