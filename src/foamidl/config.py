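"""Strict run configuration schema (YAML-backed, unknown keys rejected).

Patch width and bag size have no universally safe values — they set the
scale of every downstream tensor — so they are mandatory: a config without
``patch_proposal.width`` and ``patch_proposal.k`` does not validate.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = [
    "SynthDataConfig",
    "PatchProposalConfig",
    "PatchNetConfig",
    "AMIDLConfig",
    "ClassifierConfig",
    "FSSASection",
    "MetricsConfig",
    "RunConfig",
    "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthDataConfig(_Strict):
    shape: tuple[int, int, int] = (48, 48, 48)
    n_per_group: int = 60
    lesion_origin: tuple[int, int, int] = (24, 24, 24)
    lesion_width: int = 12
    effect_size: float = 1.5
    noise_sd: float = 1.0
    smoothness: float = 6.0
    lesion_sign: int = -1


class PatchProposalConfig(_Strict):
    width: int  # patch cube side W (voxels) — mandatory
    k: int  # bag size — mandatory
    statistic: str = "patch_mean"

    @field_validator("statistic")
    @classmethod
    def _stat(cls, v):
        if v not in ("patch_mean", "voxelwise"):
            raise ValueError(f"unknown test statistic {v!r}")
        return v


class PatchNetConfig(_Strict):
    channels: tuple[int, int, int, int] = (32, 64, 128, 128)


class AMIDLConfig(_Strict):
    hidden: int = 4
    shared_descriptor_mlp: bool = True


class ClassifierConfig(_Strict):
    lr: float = 1e-3
    epochs: int = 100
    batch_size: int = 8
    patience: int = 15
    weight_decay: float = 0.0
    attention_lr_mult: float = 1.0
    effect_supervision: float = 1.0
    conv_channels: tuple[int, int] = (16, 8)
    class_weights: str | None = None  # None or "balanced"
    ablation: tuple[str, ...] = ()
    val_fraction: float = 0.2  # of the training portion, for early stopping
    dtype: str = "float32"

    @field_validator("class_weights")
    @classmethod
    def _cw(cls, v):
        if v not in (None, "balanced"):
            raise ValueError("class_weights must be null or 'balanced'")
        return v


class FSSASection(_Strict):
    enabled: bool = True
    n_max: int = 12
    n_min: int = 6
    t_max: int = 30
    c_max: float = 0.95
    c_min: float = 0.05
    gfm_m: float = 2.0
    radius: float = 0.5
    c1_schedule: str = "adaptive"
    sort_chain: bool = False


class MetricsConfig(_Strict):
    holdout_fraction: float = 0.8
    threshold: float = 0.5


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "run"
    manifest: str | None = None  # CSV subject_id,path,label; null -> synthesize
    synthdata: SynthDataConfig = Field(default_factory=SynthDataConfig)
    patch_proposal: PatchProposalConfig
    patchnet: PatchNetConfig = Field(default_factory=PatchNetConfig)
    amidl: AMIDLConfig = Field(default_factory=AMIDLConfig)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    fssa: FSSASection = Field(default_factory=FSSASection)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
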