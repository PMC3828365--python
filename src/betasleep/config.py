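"""YAML configuration loading for the pipeline and the generator.

The file is a flat mapping with optional ``generator``, ``thresholds`` and
``bands`` blocks; any omitted key keeps its default.  Example::

    seed: 7
    generator:
      genotype: R6/1
      age_weeks: 17.5
      duration_s: 600
    thresholds:
      speed_active: 2.0
    bands:
      beta_sum: [15, 40]
"""

from __future__ import annotations

from dataclasses import fields as dc_fields

import yaml

from .errors import ConfigError
from .pipeline import PipelineConfig
from .scoring import ScoringThresholds
from .simulate import GeneratorConfig

_BAND_KEYS = {
    "beta_sum": "beta_sum_band",
    "beta_display": "beta_display_band",
    "theta_sum": "theta_sum_band",
    "delta_comod": "delta_comod_band",
    "normalization": "normalization_range",
}


def _filtered_kwargs(cls, mapping: dict) -> dict:
    names = {f.name for f in dc_fields(cls)}
    bad = set(mapping) - names
    if bad:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(bad)}")
    out = {}
    for k, v in mapping.items():
        out[k] = tuple(v) if isinstance(v, list) else v
    return out


def load_config(path) -> tuple[PipelineConfig, GeneratorConfig]:
    """Read a YAML config file into (PipelineConfig, GeneratorConfig)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")

    gen = GeneratorConfig(**_filtered_kwargs(GeneratorConfig, raw.get("generator", {})))
    thr = ScoringThresholds(**_filtered_kwargs(ScoringThresholds, raw.get("thresholds", {})))

    pipe_kwargs: dict = {"thresholds": thr}
    for short, attr in _BAND_KEYS.items():
        if short in raw.get("bands", {}):
            pipe_kwargs[attr] = tuple(raw["bands"][short])
    for key in ("seed", "prominence_threshold"):
        if key in raw:
            pipe_kwargs[key] = raw[key]
    return PipelineConfig(**pipe_kwargs), gen
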