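"""Configuration loading and validation.

A configuration is a nested mapping with sections ``network``, ``neuron``,
``plasticity``, ``protocol``, ``stimuli`` and ``training`` plus a top-level
``seed``.  Any subset may be given in a YAML/JSON file; missing keys take
the defaults below, unknown keys are rejected by name.

The plasticity thresholds are not free parameters: theta_minus is the
resting potential, theta_plus is (V_TMAX + V_Trest)/2, and the crest gate is
V_TMAX; they are derived from the neuron section at materialization.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

from .neuron import NeuronParams
from .network import NetworkConfig
from .plasticity import PlasticityParams

DEFAULTS: dict = {
    "seed": 0,
    "network": {
        "n_E": 100,
        "n_I": 20,
        "A_lat": 5.0,
        "Wmax_EI": 200.0,
        "Wmax_IE": 600.0,
        "Wmax_II": 5.0,
        "w_ff_init_max": 40.0,
        "delay_median": 4.0,
        "delay_min": 1,
        "noise_rate": 1800.0,
        "w_noise": 230.0,
        "rate_scale": 800.0,
    },
    "neuron": {
        "C": 281.0,
        "g_l": 30.0,
        "E_l": -70.6,
        "Delta_T": 2.0,
        "V_Trest": -50.4,
        "V_TMAX": -30.4,
        "tau_VT": 50.0,
        "b_wad": 80.5,
        "tau_wad": 144.0,
        "I_sp": 400.0,
        "tau_z": 40.0,
        "V_PEAK": 20.0,
    },
    "plasticity": {
        "A_LTD": 2e-3,
        "A_LTP": 0.65e-5,
        "tau_uplus": 7.0,
        "tau_uminus": 10.0,
        "tau_long": 20000.0,
        "tau_x": 15.0,
        "u_ref": 2.5,
        "gamma": 0.012,
        "w_eps": 30.0,
    },
    "protocol": {
        "stim_duration": 300,
        "blank_duration": 50,
    },
    "stimuli": {
        "image_size": 128,
        "spectral_exponent": 1.0,
        "patches_per_image": 50,
    },
    "training": {
        "n_presentations": 50_000,
        "n_test": 1_000,
    },
}


class ConfigError(ValueError):
    pass


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"section {here} must be a mapping")
            out[key] = _merge(base[key], val, here)
        else:
            if val is None or isinstance(val, (dict, list)):
                raise ConfigError(f"ill-typed value for {here}: {val!r}")
            expected = type(base[key])
            try:
                out[key] = expected(val)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"ill-typed value for {here}: {val!r}") \
                    from exc
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Load a configuration file (YAML or JSON) merged over the defaults.

    An empty or missing file yields the pure defaults.  Unknown or ill-typed
    keys raise :class:`ConfigError` naming the key.  ``overrides`` (same
    nested structure) are applied after the file.
    """
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration root must be a mapping")
        cfg = _merge(cfg, data)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def save_config(cfg: dict, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))


def materialize(cfg: dict) -> tuple[NetworkConfig, NeuronParams,
                                    PlasticityParams]:
    """Build the parameter objects from a validated configuration dict."""
    neuron = NeuronParams(**cfg["neuron"])
    net = NetworkConfig(seed=cfg["seed"], **cfg["network"])
    pl = PlasticityParams(
        theta_minus=neuron.E_l,
        theta_plus=(neuron.V_TMAX + neuron.V_Trest) / 2.0,
        crest_gate=neuron.V_TMAX,
        **cfg["plasticity"])
    return net, neuron, pl
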