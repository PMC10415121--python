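"""Defaults and YAML configuration.

Precedence is CLI flag > YAML file > packaged defaults; the effective
configuration is embedded in every JSON report for provenance.
"""

from __future__ import annotations

from typing import Optional

import yaml

from .errors import ValidationError

DEFAULTS = {
    "antisense_len": 45,
    "p10_min_pairs": 4,
    "min_target_len": 20,
    "primer_min_len": 18,
    "primer_max_len": 25,
    "tm_min": 50.0,
    "tm_max": 68.0,
    "tm_target": 60.0,
    "strict": False,
    "g_attachment": "downstream_fragment",
    "allow_wobble": True,
}


def load_config(path: Optional[str] = None, **overrides) -> dict:
    """Merge packaged defaults, an optional YAML file, and explicit overrides.

    Overrides whose value is None are ignored (unset CLI flags). Unknown
    keys are rejected so typos fail loudly.
    """
    cfg = dict(DEFAULTS)
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        unknown = set(user) - set(DEFAULTS)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    for key, value in overrides.items():
        if key not in DEFAULTS:
            raise ValidationError(f"unknown config key {key!r}")
        if value is not None:
            cfg[key] = value
    return cfg
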