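"""Schema-validated pipeline configuration.

A single YAML tree drives every stage; unknown keys are rejected up front
so a typo fails before any computation starts.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterConfig(_Strict):
    order: int = 2
    cutoff: float = 10.0
    cutoff_units: str = Field("hz", pattern="^(hz|normalized)$")


class WindowConfig(_Strict):
    seconds: float = 5.0


class StackConfig(_Strict):
    size: int = 3
    stride: int = 1


class HarConfig(_Strict):
    n_mfcc: int = 13
    n_filters: int = 20
    frame_s: float = 1.0
    hop_s: float = 0.5
    fnn_max_dim: int = 5
    fnn_rtol: float = 15.0
    fnn_atol: float = 2.0
    higuchi_k_max: int = 10
    per_window: bool = True


class LocConfig(_Strict):
    min_separation_s: float = 0.25
    threshold_mode: str = Field("abs_mean", pattern="^(abs_mean|zero|quantile)$")
    threshold_quantile: float = 0.75
    audio_n_mfcc: int = 13
    audio_n_filters: int = 26
    audio_frame_s: float = 0.025
    audio_hop_s: float = 0.010


class FeaturesConfig(_Strict):
    har: HarConfig = HarConfig()
    loc: LocConfig = LocConfig()


class SelectConfig(_Strict):
    enabled: bool = True
    keep_fraction: float = 0.5
    step_fraction: float = 0.05


class GaConfig(_Strict):
    enabled: bool = True
    n_generations: int = 10
    same_class: bool = True
    chained: bool = False


class DndfConfig(_Strict):
    hidden_layers: tuple[int, ...] = (512, 256)
    embed_dim: int = 128
    n_trees: int = 10
    tree_depth: int = 6
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-3
    l2: float = 1e-5
    class_weight: str | None = None


class EvalConfig(_Strict):
    folds: int = 10
    group_by_recording: bool = True


class PipelineConfig(_Strict):
    seed: int = 0
    fs: float = 40.0
    filter: FilterConfig = FilterConfig()
    window: WindowConfig = WindowConfig()
    stack: StackConfig = StackConfig()
    features: FeaturesConfig = FeaturesConfig()
    select: SelectConfig = SelectConfig()
    ga: GaConfig = GaConfig()
    dndf: DndfConfig = DndfConfig()
    eval: EvalConfig = EvalConfig()

    @model_validator(mode="after")
    def _check(self):
        if self.stack.size < 1 or self.stack.stride < 1:
            raise ValueError("stack size and stride must be positive")
        if not 0 < self.select.keep_fraction <= 1:
            raise ValueError("select.keep_fraction must be in (0, 1]")
        return self


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load YAML config (or defaults) and apply a nested override dict."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        data = _deep_merge(data, overrides)
    return PipelineConfig(**data)


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out
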