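"""YAML-backed configuration for the command-line workflows.

One nested mapping covers every stage; any subset may appear in a user
file and overrides the defaults key by key.
"""

from __future__ import annotations

from pathlib import Path

import yaml

DEFAULTS: dict = {
    "simulate": {"subjects": 8, "classes": [1, 2, 3, 4, 5, 6], "cycles": 30},
    "filter": {"order": 6, "band": [20.0, 450.0], "mode": "zero-phase", "filter_fmg": False},
    "window": {"length_ms": 100.0, "step_ms": 50.0},
    "onset": {"baseline_s": 1.0, "k": 5.0},
    "features": {"zc_deadband": 0.0},
    "classifier": {"family": "linear-SVM"},
    "gru": {
        "hidden_units": 150,
        "dropout": 0.2,
        "epochs": 30,
        "batch_size": 128,
        "learning_rate": 0.001,
        "lr_drop_factor": 0.1,
        "lr_drop_period": 15,
    },
    "decision": {"w_grasp_to_grasp": 2.5, "w_grasp_to_rest": 2.5},
    "evaluate": {
        "pipeline": "gru+decision",
        "train_repetitions": [1, 20],
        "test_repetitions": [21, 30],
        "n_repeats": 10,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return {k: dict(v) for k, v in DEFAULTS.items()}
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    return _merge(DEFAULTS, user)
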