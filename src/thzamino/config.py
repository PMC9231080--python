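"""Run configuration: nested sections, YAML loading, strict key checking."""

from __future__ import annotations

import copy
from typing import Any, Mapping

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "out_dir": "runs",
    "instrument": {
        "delay_range": 90.0,
        "time_step": 0.05,
        "acquisition_rate": 60.0,
        "noise_sigma_single": 0.02,
        "pulse_center_freq": 1.5,
        "pulse_delay": 15.0,
        "reference_averages": 600,
    },
    "library": {
        "separable": False,
        "peak_alpha": 3.0,
        "peak_fwhm": 0.07,
        "thickness": 1.2,
        "n_tablets": 5,
        "duration_s": 40.0,
        "avg_counts": [100, 20, 10],
        "n_echoes": 2,
        "thickness_jitter": 0.01,
        "baseline_jitter": 0.0,
    },
    "denoise": {"wavelet": "sym4", "level": 5, "mode": "soft"},
    "extraction": {
        "pad_to_ps": 100.0,
        "anchor_lo": 0.3,
        "anchor_hi": 1.0,
        "window_before": 5.0,
        "window_after": 10.0,
        "f_lo": 0.1,
        "f_hi": 2.5,
    },
    "features": {"input_mode": "hybrid", "val_frac": 0.2},
    "network": {
        "n_classes": 20,
        "input_length": 240,
        "conv1_filters": 32,
        "conv1_kernel": 7,
        "conv23_channels": 32,
        "conv23_kernel": 3,
        "conv4_channels": 64,
        "eca_gamma": 2.0,
        "eca_b": 1.0,
        "fc_sizes": [256, 128],
        "use_eca": True,
    },
    "training": {
        "epochs": 300,
        "fine_tune_epochs": 100,
        "learning_rate": 1.0e-3,
        "fine_tune_lr": 1.0e-4,
        "lr_decay": 1.0e-5,
        "momentum": 0.9,
        "batch_size": 128,
        "patience": 30,
    },
    "evaluation": {"measure_fps": False},
}


def merge_config(base: Mapping[str, Any], override: Mapping[str, Any], path: str = "") -> dict:
    """Deep-merge ``override`` into ``base``; unknown keys are rejected."""
    out = copy.deepcopy(dict(base))
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in out:
            raise KeyError(f"unknown configuration key: {where}")
        if isinstance(out[key], Mapping) and isinstance(value, Mapping):
            out[key] = merge_config(out[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | None = None) -> dict:
    """The default configuration, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    if not isinstance(override, Mapping):
        raise ValueError(f"config file {path} must contain a mapping")
    return merge_config(DEFAULT_CONFIG, override)
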