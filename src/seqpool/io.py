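"""Configuration, presets, trace I/O and the noisy-fixture generator.

Parameter sets are flat key→value mappings using the table symbols of
the chromaffin-cell literature (``k1Max``, ``K_M``, ``k_minus1``,
``k20``, ``k2cat``, ``k_minus20``, ``K_D``, ``n``, ``k3``, ``k_minus3``,
``k4`` for the sequential model; ``k2``, ``k_minus2``, ``k3s`` … for the
parallel one).  Two named presets ship the published wild-type values:
``spm_table1`` and ``ppm_table2``; ``ppm_cat`` extends the latter with
the sequential model's catalyst on the SRP→RRP step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .integrate import CalciumProtocol, Segment, SolverSettings, Trace, integrate
from .models import CatalystParams, ParallelPoolModel, PPMParams, \
    SequentialPoolModel, SPMParams

__all__ = ["PRESETS", "preset_params", "build_model", "RunConfig",
           "load_config", "write_trace", "read_trace", "write_fit_json",
           "generate_fixture"]

logger = logging.getLogger("seqpool")

# table-symbol -> dataclass-field spellings that differ
_KEY_ALIASES = {"k1Max": "k1max"}

_SPM_KEYS = {"k1Max", "K_M", "k_minus1", "k20", "k2cat", "k_minus20",
             "K_D", "n", "k3", "k_minus3", "k4"}
_PPM_KEYS = {"k1Max", "K_M", "k_minus1", "k2", "k_minus2",
             "k3s", "k_minus3s", "k4s", "k3r", "k_minus3r", "k4r"}
_CAT_KEYS = {"k20", "k2cat", "k_minus20", "K_D", "n"}

PRESETS: dict[str, dict[str, Any]] = {
    "spm_table1": {"model": "spm"},
    "ppm_table2": {"model": "ppm"},
    "ppm_cat": {"model": "ppm-cat"},
}


def _apply_overrides(cls, overrides: dict, allowed: set[str], **extra):
    unknown = set(overrides) - allowed
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    kwargs = {_KEY_ALIASES.get(k, k): v for k, v in overrides.items()}
    return cls(**kwargs, **extra)


def preset_params(name: str, overrides: Optional[dict] = None):
    """Parameter object for a named preset, with optional overrides.

    Overrides use table-symbol keys; validation (nonnegativity, K_D > 0,
    …) runs in the parameter constructors, so an invalid override such
    as ``k4 = -1`` raises immediately.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    overrides = dict(overrides or {})
    model = PRESETS[name]["model"]
    if model == "spm":
        return _apply_overrides(SPMParams, overrides, _SPM_KEYS)
    cat_over = overrides.pop("catalyst", None)
    if model == "ppm":
        if cat_over is not None:
            raise ValueError("catalyst overrides require the ppm_cat preset")
        return _apply_overrides(PPMParams, overrides, _PPM_KEYS)
    catalyst = _apply_overrides(CatalystParams, dict(cat_over or {}), _CAT_KEYS)
    return _apply_overrides(PPMParams, overrides, _PPM_KEYS, catalyst=catalyst)


def build_model(model_name: str, overrides: Optional[dict] = None,
                unclamped: bool = False, destabilization: float = 1.0):
    """Construct a model object from a model name and overrides."""
    if model_name == "spm":
        return SequentialPoolModel(preset_params("spm_table1", overrides),
                                   unclamped=unclamped,
                                   destabilization=destabilization)
    if unclamped or destabilization != 1.0:
        raise ValueError("syt-null modifiers apply to the sequential model only")
    if model_name == "ppm":
        return ParallelPoolModel(preset_params("ppm_table2", overrides))
    if model_name == "ppm-cat":
        return ParallelPoolModel(preset_params("ppm_cat", overrides))
    raise ValueError(f"unknown model {model_name!r} (spm, ppm, ppm-cat)")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Fully validated run description (model + protocol + solver + noise)."""

    model_name: str = "spm"
    params: Any = None  # SPMParams | PPMParams
    model: Any = None
    protocol: Optional[CalciumProtocol] = None
    solver: SolverSettings = field(default_factory=SolverSettings)
    noise_sd: float = 0.0
    seed: int = 0
    out_dir: Optional[Path] = None


_TOP_KEYS = {"model", "params", "variant", "protocol", "solver", "noise",
             "out_dir"}
_SEGMENT_KEYS = {"t_start", "kind", "level", "tau", "target"}
_VARIANT_KEYS = {"unclamped", "destabilization"}
_NOISE_KEYS = {"sd", "seed"}


def _protocol_from_spec(spec) -> CalciumProtocol:
    segments = []
    for i, seg in enumerate(spec):
        unknown = set(seg) - _SEGMENT_KEYS
        if unknown:
            raise ValueError(f"protocol segment {i}: unknown keys {sorted(unknown)}")
        segments.append(Segment(**seg))
    return CalciumProtocol(segments)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Unknown keys are rejected at every level; an empty file yields the
    defaults (sequential model with the published wild-type parameters,
    no protocol).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")

    model_name = raw.get("model", "spm")
    variant = dict(raw.get("variant") or {})
    bad = set(variant) - _VARIANT_KEYS
    if bad:
        raise ValueError(f"{path}: unknown variant keys {sorted(bad)}")
    model = build_model(model_name, raw.get("params"),
                        unclamped=bool(variant.get("unclamped", False)),
                        destabilization=float(variant.get("destabilization", 1.0)))

    protocol = None
    if raw.get("protocol") is not None:
        protocol = _protocol_from_spec(raw["protocol"])

    solver_spec = dict(raw.get("solver") or {})
    allowed = {f.name for f in fields(SolverSettings)}
    bad = set(solver_spec) - allowed
    if bad:
        raise ValueError(f"{path}: unknown solver keys {sorted(bad)}")
    solver = SolverSettings(**solver_spec)

    noise = dict(raw.get("noise") or {})
    bad = set(noise) - _NOISE_KEYS
    if bad:
        raise ValueError(f"{path}: unknown noise keys {sorted(bad)}")
    sd = float(noise.get("sd", 0.0))
    if sd < 0:
        raise ValueError(f"{path}: noise sd must be >= 0")

    return RunConfig(model_name=model_name, params=model.params, model=model,
                     protocol=protocol, solver=solver, noise_sd=sd,
                     seed=int(noise.get("seed", 0)),
                     out_dir=Path(raw["out_dir"]) if raw.get("out_dir") else None)


# ---------------------------------------------------------------------------
# Trace and fit I/O
# ---------------------------------------------------------------------------


def write_trace(trace: Trace, path) -> None:
    """Write a trace as CSV (t_s, ca_uM, one column per pool, dCm_fF)."""
    trace.to_dataframe().to_csv(path, index=False,
                                float_format="%.17g")


def read_trace(path) -> Trace:
    """Read a trace CSV written by :func:`write_trace`.

    Any two-column (t_s, dCm_fF) table is also accepted for fitting
    externally measured capacitance traces; pool columns are then empty.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    if "t_s" not in df.columns or "dCm_fF" not in df.columns:
        raise ValueError(f"{path}: required columns t_s and dCm_fF not found "
                         f"(got {list(df.columns)})")
    t = df["t_s"].to_numpy(float)
    dCm = df["dCm_fF"].to_numpy(float)
    ca = df["ca_uM"].to_numpy(float) if "ca_uM" in df.columns else np.full_like(t, np.nan)
    pool_cols = [c for c in df.columns if c not in ("t_s", "ca_uM", "dCm_fF")]
    pools = df[pool_cols].to_numpy(float) if pool_cols else np.empty((t.size, 0))
    return Trace(t=t, ca=ca, pools=pools, dCm=dCm,
                 state_names=tuple(pool_cols))


def write_fit_json(fit, path) -> None:
    """Write a burst fit as JSON with symbol-named keys."""
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Fixture generator
# ---------------------------------------------------------------------------


def generate_fixture(model, protocol: CalciumProtocol,
                     t_span: tuple[float, float], noise_sd: float,
                     seed: int,
                     settings: Optional[SolverSettings] = None) -> Trace:
    """Simulate a trace and add seeded Gaussian noise to the capacitance.

    Noise models the capacitance measurement and is applied to ``dCm``
    only; the pool series stay clean.  Identical (model, protocol, seed)
    give bit-identical fixtures; ``noise_sd = 0`` returns the clean
    trace.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    trace = integrate(model, protocol, t_span, settings=settings, init="steady")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace.dCm = trace.dCm + rng.normal(0.0, noise_sd, size=trace.dCm.shape)
    logger.info("fixture: seed=%d noise_sd=%g span=%s", seed, noise_sd, t_span)
    return trace
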