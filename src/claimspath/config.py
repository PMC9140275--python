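"""Loaders for the editable configuration shipped with the package.

All code lists (regimen taxonomy, Charlson map, complication sets) and rate
tables live as plain YAML/CSV files under ``claimspath/config`` so they can be
replaced per study without touching code.
"""

from __future__ import annotations

import functools
from importlib import resources

import pandas as pd
import yaml


def _read_text(name: str) -> str:
    return resources.files("claimspath").joinpath("config", name).read_text()


@functools.lru_cache(maxsize=None)
def load_regimen_config(path: str | None = None) -> dict:
    """Drug->component map and hierarchical regimen category definitions."""
    text = open(path).read() if path else _read_text("regimens.yaml")
    cfg = yaml.safe_load(text)
    for cat in cfg["categories"]:
        cat["required"] = set(cat["required"])
        cat["any_of"] = set(cat.get("any_of", ()))
    cfg["conditioning_sets"] = {
        k: set(v) for k, v in cfg["conditioning_sets"].items()
    }
    cfg["immunotherapy_components"] = set(cfg["immunotherapy_components"])
    cfg["chemo_components"] = set(cfg["chemo_components"])
    return cfg


@functools.lru_cache(maxsize=None)
def load_cci_map(path: str | None = None) -> dict:
    """Quan ICD-10 Charlson category map with weights and hierarchy rules."""
    text = open(path).read() if path else _read_text("quan_cci.yaml")
    return yaml.safe_load(text)


@functools.lru_cache(maxsize=None)
def load_complication_codes(path: str | None = None) -> dict:
    """ICD-10 prefix sets for heart/kidney/liver treatment complications."""
    text = open(path).read() if path else _read_text("complications.yaml")
    return {k: tuple(v) for k, v in yaml.safe_load(text).items()}


def load_rates_csv(path: str | None = None) -> pd.DataFrame:
    if path:
        return pd.read_csv(path)
    with resources.as_file(
        resources.files("claimspath").joinpath("config", "rates.csv")
    ) as p:
        return pd.read_csv(p)
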