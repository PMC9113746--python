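"""Flat YAML run configuration, merged with command-line flags (CLI wins)."""

from __future__ import annotations

from pathlib import Path

import yaml

#: Every recognized configuration key with its default.  The config file is
#: flat; unknown keys are rejected so typos fail loudly.
DEFAULTS: dict = {
    "unit": "TPM",
    "pseudocount": 0.01,
    "min_tpm_marker": 5.0,
    "min_fold_marker": 50.0,
    "min_tpm_zscore": 2.0,
    "min_tpm_regression": 1.0,
    "max_outliers": 5,
    "resid_threshold": 4.0,
    "alpha": 0.05,
    "min_fold_regulated": 2.0,
    "k_clusters": 6,
    "intermediate_tol": 0.5,
    "max_censor_steps": 50,
    "log_space": True,
    "seed": 0,
}


def load_config(path: str | Path | None) -> dict:
    """Read a flat YAML config and overlay it on the defaults."""
    merged = dict(DEFAULTS)
    if path is None:
        return merged
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a flat mapping")
    unknown = set(raw) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    merged.update(raw)
    return merged


def merge_cli(config: dict, **cli_values) -> dict:
    """Overlay explicitly supplied CLI values (None means 'not given')."""
    merged = dict(config)
    for key, value in cli_values.items():
        if value is not None:
            if key not in DEFAULTS:
                raise ValueError(f"unknown option {key!r}")
            merged[key] = value
    return merged
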