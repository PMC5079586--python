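"""Flat YAML configuration handling.

A run is configured by one flat key/value file holding the life-history
block plus module defaults; :func:`load_config` resolves it to a dict and
logs the resolved values so every report is traceable to its inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import yaml

from .core_data import LifeHistory

logger = logging.getLogger(__name__)

LIFE_HISTORY_KEYS = (
    "l_inf", "cv_linf", "m_nat", "k_growth", "m_over_k", "t0",
    "lm50", "lm95", "fec_b", "am", "tmax", "max_len",
)


def load_config(path) -> dict:
    """Read a flat YAML key/value file; nested mappings are rejected."""
    text = Path(path).read_text(encoding="utf-8")
    cfg = yaml.safe_load(text) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a key/value mapping")
    for key, val in cfg.items():
        if isinstance(val, (dict, list)):
            raise ValueError(f"config key {key!r} is nested; flat keys only")
    logger.info("resolved config from %s: %s", path, cfg)
    return cfg


def life_history_from_config(cfg: dict) -> LifeHistory:
    """Build a :class:`LifeHistory` from the life-history keys of a config."""
    kwargs = {k: cfg[k] for k in LIFE_HISTORY_KEYS if cfg.get(k) is not None}
    return LifeHistory(**kwargs)
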