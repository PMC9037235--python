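"""Run configuration: one strictly validated JSON document per run.

Unknown keys are rejected so typos fail loudly; the resolved
configuration is written beside every run's outputs for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .agreement import AcceptanceSpec
from .postprocess import PostprocessConfig
from .segment import FeatureConfig
from .simulate import SceneConfig

__all__ = ["RunConfig", "ForestParams", "MetricsParams", "load_run_config"]


@dataclass(frozen=True)
class ForestParams:
    n_trees: int = 100
    max_depth: int | None = 20
    max_pixels_per_class: int = 10_000


@dataclass(frozen=True)
class MetricsParams:
    min_cells: int = 500
    rule: str = "el_hoss_2018"
    pit_size_average: str = "per_pit"


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    output_dir: str = "pitcount_out"
    verbosity: int = 1
    n_train_images: int = 6
    n_test_images: int = 6
    scene: SceneConfig = field(default_factory=SceneConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    forest: ForestParams = field(default_factory=ForestParams)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    metrics: MetricsParams = field(default_factory=MetricsParams)
    agreement: AcceptanceSpec = field(default_factory=AcceptanceSpec)


_SECTIONS = {
    "scene": SceneConfig,
    "features": FeatureConfig,
    "forest": ForestParams,
    "postprocess": PostprocessConfig,
    "metrics": MetricsParams,
    "agreement": AcceptanceSpec,
}

_TUPLE_FIELDS = {"cell_radius_um_range", "pit_radius_um_range", "scales_px"}


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key {sorted(unknown)[0]!r} in {context} config")
    kwargs = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
        for k, v in data.items()
    }
    return cls(**kwargs)


def run_config_from_dict(data: dict) -> RunConfig:
    data = dict(data)
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            section = data.pop(name)
            if not isinstance(section, dict):
                raise ValueError(f"section {name!r} must be a mapping")
            kwargs[name] = _build(cls, section, name)
    top = _build(RunConfig, data, "top-level")
    return dataclasses.replace(top, **kwargs)


def run_config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["scene"] = cfg.scene.to_dict()
    d["features"]["scales_px"] = list(cfg.features.scales_px)
    return d


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        return run_config_from_dict(json.load(fh))


def save_run_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(run_config_to_dict(cfg), indent=2, sort_keys=True) + "\n")
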