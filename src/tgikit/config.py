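"""Shared YAML/JSON configuration for the CLI.

One file configures everything; top-level keys ``cohort`` (fields of
:class:`~tgikit.synthetic_cohort.CohortSpec`) and ``fit`` (fields of
:class:`~tgikit.population_fit.FitConfig`) are each optional and merged
over the defaults.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path
from typing import Optional

import yaml

from .population_fit import FitConfig
from .synthetic_cohort import CohortSpec

__all__ = ["load_config", "cohort_spec_from_config", "fit_config_from_config"]


def load_config(path: Optional[str]) -> dict:
    """Load a YAML (or JSON, a YAML subset) config file; empty dict if None."""
    if path is None:
        return {}
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return data


def _build(cls, section: dict, name: str):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown {name} option(s): {sorted(unknown)}")
    # YAML lists -> tuples where the dataclass expects tuples
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
    }
    return cls(**coerced)


def cohort_spec_from_config(config: dict) -> CohortSpec:
    return _build(CohortSpec, config.get("cohort", {}), "cohort")


def fit_config_from_config(config: dict) -> FitConfig:
    return _build(FitConfig, config.get("fit", {}), "fit")
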