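"""Default analysis thresholds and YAML configuration loading.

Every threshold used by the pipeline lives here with its default; a YAML
config file overrides keys selectively.
"""

from __future__ import annotations

from pathlib import Path

import yaml

DEFAULTS: dict = {
    # co-regulation network
    "network": {
        "r_min": 0.95,
        "alpha": 0.01,
        "null_pairs": 50_000,
        "null_shuffles": 10,
        "block_size": 1024,
    },
    # differential abundance
    "dap": {
        "fc_threshold": 2.0,
        "alpha": 0.05,
        "equal_var": True,
    },
    "clustering": {
        "k": 10,
        "metric": "correlation",
        "linkage": "average",
    },
    # gene-set filtering
    "gene_sets": {
        "min_detected": 3,   # "more than two members detected"
        "max_go_size": 150,
    },
    "cooperativity": {
        "edge_sign": "positive",
        "alpha": 0.05,
        "min_module_members": 3,
    },
    "discordance": {
        "threshold": 1.0,
        "tf_target_r_min": 0.9,
        "transition_test": "paired_t",
        "pseudocount": 1.0,
    },
    "phospho": {
        "min_substrates": 2,
        "r_min": 0.5,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return _deep_merge(DEFAULTS, {})
    with open(path, encoding="utf-8") as fh:
        override = yaml.safe_load(fh) or {}
    return _deep_merge(DEFAULTS, override)
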