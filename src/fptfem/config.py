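"""YAML run configurations and the safe expression-based custom family.

A configuration selects one of the built-in model families (by name, with
either explicit parameter values or unit-cube coordinates rho), or a
``custom`` family whose drift and boundaries are given as arithmetic
expression strings in ``t``, ``x`` and user parameters.  Expressions are
parsed by sympy and compiled to vectorized numpy callables; no Python
evaluation of untrusted strings takes place.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import sympy as sp
import yaml

from .models import FAMILIES, DecisionModel

__all__ = ["load_config", "model_from_config", "config_hash"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _compile_expr(expr: str, params: dict, want_x: bool):
    t, x = sp.symbols("t x")
    loc = {"t": t, "x": x, **{k: sp.Float(v) for k, v in params.items()}}
    tree = sp.sympify(expr, locals=loc)
    extra = tree.free_symbols - {t, x}
    if extra:
        raise ValueError(f"unknown symbols {extra} in expression {expr!r}")
    args = (t, x) if want_x else (t,)
    fn = sp.lambdify(args, tree, modules="numpy")

    if want_x:
        def wrapped(tv, xv):
            tv, xv = np.asarray(tv, float), np.asarray(xv, float)
            out = fn(tv, xv)
            return np.broadcast_to(np.asarray(out, float),
                                   np.broadcast(tv, xv).shape).copy()
    else:
        def wrapped(tv):
            tv = np.asarray(tv, float)
            out = fn(tv)
            return np.broadcast_to(np.asarray(out, float), tv.shape).copy()
    return wrapped


def _custom_model(cfg: dict) -> DecisionModel:
    custom = cfg["custom"]
    params = dict(custom.get("params", {}))
    required = ["mu", "dmu_dx", "alpha", "beta", "dalpha", "dbeta"]
    missing = [k for k in required if k not in custom]
    if missing:
        raise ValueError(f"custom family missing expressions: {missing}")
    return DecisionModel(
        sigma=float(cfg.get("sigma", 1.0)),
        mu=_compile_expr(custom["mu"], params, True),
        dmu_dx=_compile_expr(custom["dmu_dx"], params, True),
        alpha=_compile_expr(custom["alpha"], params, False),
        beta=_compile_expr(custom["beta"], params, False),
        dalpha=_compile_expr(custom["dalpha"], params, False),
        dbeta=_compile_expr(custom["dbeta"], params, False),
        tau=float(cfg["tau"]),
        y0=cfg.get("y0"),
        name="custom",
        params=params,
    )


def model_from_config(cfg: dict, rho: Optional[np.ndarray] = None) -> DecisionModel:
    """Instantiate the configured decision model (rho overrides the config)."""
    family = cfg.get("family", "custom")
    if family == "custom":
        return _custom_model(cfg)
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from "
                         f"{sorted(FAMILIES)} or 'custom'")
    build, box = FAMILIES[family]
    if rho is None:
        if "rho" in cfg:
            rho = np.asarray(cfg["rho"], dtype=float)
        elif "params" in cfg:
            theta = [cfg["params"][name] for name in box.names]
            rho = box.unmap(theta)
        else:
            rho = np.zeros(box.N)
    return build(rho)
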