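"""Schema-validated pipeline configuration.

A :class:`RunConfig` fixes one root seed, per-stage toggles, and every
tunable parameter of the demo pipeline.  Unknown keys are rejected at
validation time (typos fail fast, before any stage runs).
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WaveStageConfig(_Strict):
    enabled: bool = True
    n_trials: int = 30
    n_channels: int = 7
    duration_s: float = 1.0
    fs_hz: float = 250.0
    frequency_hz: float = 10.0
    # dB-vs-baseline cancels pure amplitude scaling, so the planted condition
    # difference is an SNR difference: strong coherent alpha wave under IH,
    # weak under NP, same noise floor.
    amplitude_ih: float = 1.2
    amplitude_np: float = 0.4
    phase_step_rad_per_channel: float = 0.8
    # Broadband noise at realistic single-trial level: the oscillation is a
    # minority of total variance, so the dB-vs-baseline measure retains
    # sensitivity to the planted SNR difference.
    noise_sd: float = 4.0
    bands: list[str] = Field(default_factory=lambda: ["theta", "alpha", "beta", "gamma"])


class ChangepointStageConfig(_Strict):
    enabled: bool = True
    n_samples: int = 600
    fs_hz: float = 100.0
    change_time_s: float = 3.0
    level_pre: float = 0.75
    level_post: float = 0.55
    noise_sd: float = 0.03
    window: tuple[float, float] = (0.5, 5.5)
    min_size: int = 2


class DecodingStageConfig(_Strict):
    enabled: bool = True
    n_trials_per_condition: int = 25
    n_runs: int = 5
    n_features: int = 100
    condition_separation: float = 2.0
    feature_coupling: float = 0.3
    noise_sd: float = 1.0
    n_boot: int = 100
    n_components: int | None = 20
    feature_trials_per_condition: int = 40


class RsaStageConfig(_Strict):
    enabled: bool = True
    # A single latent feature axis dilutes with feature count, so the RSA
    # demo uses a compact region (20 features) where the planted coupling
    # contrast is recoverable from 30 stimuli.
    n_trials_per_condition: int = 30
    n_features: int = 20
    coupling_np: float = 0.7
    coupling_ih: float = 0.1
    n_perm: int = 5000


class InferStageConfig(_Strict):
    enabled: bool = True
    n_subjects: int = 36
    pre_contrast: float = -0.1
    post_contrast: float = -0.5
    beta_noise_sd: float = 0.3
    boundary_s: float = 3.0
    p_np: float = 0.85
    p_ih: float = 0.55
    n_behavior_trials: int = 40
    subject_sd: float = 0.4
    behavior_neural_slope: float = 1.0
    mediation_n: int = 200
    mediation_a: float = 0.5
    mediation_b: float = 0.4
    mediation_c_prime: float = 0.2
    n_boot: int = 5000


class RunConfig(_Strict):
    """Root configuration: one seed, per-stage parameter blocks."""

    seed: int = 0
    waves: WaveStageConfig = Field(default_factory=WaveStageConfig)
    changepoint: ChangepointStageConfig = Field(default_factory=ChangepointStageConfig)
    decoding: DecodingStageConfig = Field(default_factory=DecodingStageConfig)
    rsa: RsaStageConfig = Field(default_factory=RsaStageConfig)
    inference: InferStageConfig = Field(default_factory=InferStageConfig)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) config file."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return RunConfig.model_validate(raw)
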