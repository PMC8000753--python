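"""YAML configuration loading for the pipeline and CLI.

The configuration mirrors :class:`osteofem.validate.PipelineConfig`; every
key is optional and defaults to the study conditions.  Nested sections:
``scaffold``, ``curves``, ``volume``, ``bone``, and flat pipeline keys
(``fe_levels``, ``element_size``, ...).
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .fem import ElasticConstants
from .geometry import ScaffoldParams
from .synth import CurveSpec, VolumeSpec
from .validate import PipelineConfig


def _build(cls, section: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(section) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if "shape" in section:
        section = {**section, "shape": tuple(section["shape"])}
    return cls(**section)


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, cls in (("scaffold", ScaffoldParams), ("curve_spec", CurveSpec),
                     ("volume_spec", VolumeSpec), ("bone", ElasticConstants)):
        section = raw.pop({"curve_spec": "curves", "volume_spec": "volume"}.get(key, key), None)
        if section is not None:
            kwargs[key] = _build(cls, section)
    for key in ("fe_levels", "densito_levels", "densito_delta_phi"):
        if key in raw:
            raw[key] = tuple(raw[key])
    pipeline_names = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - pipeline_names
    if unknown:
        raise ValueError(f"unknown pipeline keys: {sorted(unknown)}")
    kwargs.update(raw)
    return PipelineConfig(**kwargs)
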