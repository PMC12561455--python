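"""Run configuration: defaults, YAML loading and deep merging.

Every tunable used by the pipeline lives here so that a single resolved
mapping can be written next to any output for reproducibility.
"""
from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Any, Mapping

import yaml

DEFAULTS: dict[str, Any] = {
    "imputation": {
        # missing cells get a uniform draw from (m/divisor_low, m/divisor_high)
        # where m is the smallest non-missing normalized abundance
        "divisor_low": 500000.0,
        "divisor_high": 5000.0,
        "seed": 0,
        # "all" imputes the whole matrix; "informative" only the peptides
        # consumed by the classifier and correlation stages
        "scope": "all",
    },
    "informative": {
        "presence_frac": 0.25,
        "variation_min": 0.03,
        "variation_statistic": "cv",  # or "relrange"
    },
    "panel": {
        "n_top": 11,
    },
    "classifier": {
        "n_trees": 500,
        "seed": 0,
    },
    "correlation": {
        "method": "pearson",  # or "spearman"
        "min_shared_peptides": 3,
        # "pairwise_complete" correlates over co-observed peptides only;
        # "imputed" correlates full vectors after minimum-anchored imputation
        "missing_policy": "pairwise_complete",
    },
    "cutoffs": {
        "in_db": 0.6,
        "submission_qc": 0.7,
    },
    "prediction": {
        "floor_negative_correlations": True,
    },
}


def deep_merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    """Recursively merge ``override`` into ``base`` without mutating either."""
    merged = copy.deepcopy(dict(base))
    for key, value in override.items():
        if key in merged and isinstance(merged[key], Mapping) and isinstance(value, Mapping):
            merged[key] = deep_merge(merged[key], value)
        else:
            merged[key] = copy.deepcopy(value)
    return merged


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Resolve DEFAULTS <- YAML file <- explicit overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, Mapping):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg = deep_merge(cfg, loaded)
    if overrides:
        cfg = deep_merge(cfg, overrides)
    return cfg


def dump_config(cfg: Mapping[str, Any], path: str | Path) -> None:
    """Write a resolved-config snapshot next to run outputs."""
    Path(path).write_text(json.dumps(cfg, indent=2, sort_keys=True) + "\n")
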