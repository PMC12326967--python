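"""Structured YAML configuration for models, cohorts and run settings."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional, Union

import yaml

from .cohort import CohortSpec, _LogNormalSpec
from .model import PopulationModel, final_model, model_from_dict, model_to_dict

__all__ = [
    "load_config",
    "dump_config",
    "config_hash",
    "model_from_config",
    "cohort_spec_from_config",
]


def load_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_config(cfg: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    """Stable digest of the semantic content of a configuration."""
    canon = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def model_from_config(cfg: Optional[dict]) -> PopulationModel:
    """Model from the ``model`` section; packaged final model if absent."""
    if not cfg or "model" not in cfg:
        return final_model()
    return model_from_dict(cfg["model"])


def model_to_config(model: PopulationModel) -> dict:
    return {"model": model_to_dict(model)}


_DIST_KEYS = ("ga", "pma", "wt", "scr")


def cohort_spec_from_config(cfg: Optional[dict]) -> CohortSpec:
    """Cohort spec from the ``cohort`` section (defaults when absent).

    Distribution entries take the form
    ``{median: m, iqr: [lo, hi], bounds: [lo, hi]}``.
    """
    if not cfg or "cohort" not in cfg:
        return CohortSpec()
    section = dict(cfg["cohort"])
    kw = {}
    for key in _DIST_KEYS:
        if key in section:
            d = section.pop(key)
            kw[key] = _LogNormalSpec(
                median=float(d["median"]),
                iqr=tuple(float(v) for v in d["iqr"]),
                bounds=tuple(float(v) for v in d["bounds"]),
            )
    kw.update(section)
    return CohortSpec(**kw)
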