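"""YAML configuration parsing for grammars, intensities and scenarios."""

from __future__ import annotations

import math
from pathlib import Path

import yaml

from .forest import Component, Domain, SpeciesSpec, SquaredExponentialMixture, UniformIntensity
from .lsystem import Grammar, GeometryParams


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def grammar_from_config(cfg: dict) -> Grammar:
    """Keys: variables (list of chars), axiom (str), rules (map var -> str)."""
    return Grammar(
        variables=frozenset(cfg["variables"]),
        axiom=cfg["axiom"],
        productions=dict(cfg.get("rules", {})),
    )


def geometry_from_config(cfg: dict) -> GeometryParams:
    """geometry.* keys mirror GeometryParams fields; angles given in degrees."""
    kwargs = dict(cfg)
    for key in ("branch_angle", "angle_noise_sd"):
        if key in kwargs:
            kwargs[key] = math.radians(kwargs[key])
    if "raise_fraction_range" in kwargs:
        kwargs["raise_fraction_range"] = tuple(kwargs["raise_fraction_range"])
    return GeometryParams(**kwargs)


def domain_from_config(cfg) -> Domain:
    if isinstance(cfg, dict):
        return Domain(**cfg)
    x0, x1, y0, y1 = cfg
    return Domain(x0, x1, y0, y1)


def mixture_from_config(cfg: dict):
    """Keys: domain ([x0,x1,y0,y1] or map) and either ``rate`` (homogeneous)
    or ``components`` (list of {C, cx, cy, h, l})."""
    domain = domain_from_config(cfg["domain"])
    if "rate" in cfg:
        return UniformIntensity(rate=cfg["rate"], domain=domain)
    comps = tuple(Component(**c) for c in cfg["components"])
    return SquaredExponentialMixture(components=comps, domain=domain)


def species_from_config(cfg: list[dict]) -> list[SpeciesSpec]:
    specs = []
    for entry in cfg:
        tree_cfg = dict(entry.get("tree", {}))
        if "grammar" in tree_cfg:
            tree_cfg["grammar"] = grammar_from_config(tree_cfg["grammar"])
        if "geometry" in tree_cfg:
            tree_cfg["geometry"] = geometry_from_config(tree_cfg["geometry"])
        specs.append(
            SpeciesSpec(
                label=entry["label"],
                mixture=mixture_from_config(entry["intensity"]),
                tree_config=tree_cfg,
            )
        )
    return specs
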