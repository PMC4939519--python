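"""Run configuration: defaults, YAML config files, and flag overrides.

Precedence is flags > config file > defaults. The effective configuration is
echoed to the log and embedded in every manifest and summary a subcommand
writes, so any output can be traced back to the thresholds that produced it.
"""
from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import yaml

from .ce_align import AlignConfig
from .predictor import PredictorConfig
from .template_db import DbConfig

logger = logging.getLogger(__name__)

__all__ = ["load_config", "config_snapshot"]

_DB_KEYS = {"max_resolution", "min_chain_len", "min_ligand_atoms",
            "stability_dist", "bound_site_radius", "length_tolerance"}
_ALIGN_KEYS = {"afp_len", "d_intra", "d_join", "gap_max", "max_afps"}
_PRED_KEYS = {"cluster_radius", "top_templates", "unbound_site_radius",
              "max_sites", "site_from_cluster_union"}


class ConfigError(ValueError):
    pass


def load_config(path=None, **overrides) -> PredictorConfig:
    """Build the effective :class:`PredictorConfig`.

    ``path`` is an optional flat YAML file of ``field: value`` pairs using the
    config field names; ``overrides`` are flag values (None values ignored)
    that take precedence over the file. Out-of-range values raise a
    :class:`ConfigError` naming the offending field.
    """
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config file must be a mapping")
        values.update(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(values) - _DB_KEYS - _ALIGN_KEYS - _PRED_KEYS
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    try:
        db = DbConfig(**{k: v for k, v in values.items() if k in _DB_KEYS})
        al = AlignConfig(**{k: v for k, v in values.items() if k in _ALIGN_KEYS})
        cfg = PredictorConfig(
            db=db, align=al,
            **{k: v for k, v in values.items() if k in _PRED_KEYS})
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    logger.info("effective config: %s", config_snapshot(cfg))
    return cfg


def config_snapshot(cfg: PredictorConfig) -> dict:
    """Flat dict of every effective threshold, for embedding in outputs."""
    out = {k: v for k, v in asdict(cfg).items() if k not in ("db", "align")}
    out.update(asdict(cfg.db))
    out.update(asdict(cfg.align))
    return out
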