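"""Presets, configuration, pipeline orchestration and run records.

The preset table bundles the reference parameter sets used throughout the
analyses; sweep presets carry a default value for the swept parameter plus
the sweep range.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model_core import ModelParams

__all__ = ["Preset", "RunRecord", "PRESETS", "load_preset", "load_config",
           "params_from_mapping", "run_pipeline"]


@dataclass(frozen=True)
class Preset:
    name: str
    params: ModelParams
    provenance: str
    expected: Dict[str, object] = field(default_factory=dict)
    sweep: Optional[Tuple[str, float, float]] = None  # (parameter, lo, hi)
    alt_eps: Tuple[float, ...] = ()


def _mp(a, kappa, d1, d2, d3, rho, eps):
    return ModelParams(a=a, kappa=kappa, delta1=d1, delta2=d2, delta3=d3,
                       rho=rho, eps=eps)


PRESETS: Dict[str, Preset] = {
    p.name: p
    for p in [
        Preset(
            "fig1", _mp(0.35, 0.1, 12.5, 0.1, 70.0, 1.0, 0.0063),
            "2D fingering simulation; wave speed c = 0.0401",
            expected={"regime": "malignant_gap", "sign_lambda_c2": +1,
                      "c": 0.0401},
        ),
        Preset(
            "fig7", _mp(0.1, 0.1, 4.0, 0.1, 70.0, 1.0, 0.0063),
            "gap width vs delta1 continuation",
            sweep=("delta1", 0.1, 15.0), alt_eps=(1e-4,),
        ),
        Preset(
            "fig8_row1", _mp(0.1, 0.1, 12.5, 0.1, 70.0, 1.0, 0.0063),
            "1D-stable gap front, transversally unstable",
            expected={"regime": "malignant_gap", "sign_lambda_c2": +1},
        ),
        Preset(
            "fig8_row2", _mp(0.25, 0.1, 12.5, 0.1, 70.0, 1.0, 0.0063),
            "1D-stable gap front, transversally unstable",
            expected={"regime": "malignant_gap", "sign_lambda_c2": +1},
        ),
        Preset(
            "fig8_row3", _mp(0.35, 0.1, 12.5, 0.1, 70.0, 1.0, 0.0063),
            "1D-stable gap front, transversally unstable (same as fig1)",
            expected={"regime": "malignant_gap", "sign_lambda_c2": +1},
        ),
        Preset(
            "fig8_row4", _mp(0.25, 0.05, 11.5, 3.0, 1.0, 15.0, 0.05),
            "1D-stable gap front, transversally unstable",
            expected={"regime": "malignant_gap", "sign_lambda_c2": +1},
        ),
        Preset(
            "fig9", _mp(0.1, 0.1, 12.5, 0.1, 70.0, 1.0, 0.0063),
            "continuation in delta1: c and lambda_c2 vs delta1",
            sweep=("delta1", 0.05, 15.0),
        ),
        Preset(
            "fig10_low", _mp(0.1, 0.1, 0.6, 0.1, 70.0, 1.0, 0.0063),
            "continuation in a at delta1 = 0.6",
            sweep=("a", 0.05, 0.45),
        ),
        Preset(
            "fig10_high", _mp(0.1, 0.1, 12.5, 0.1, 70.0, 1.0, 0.0063),
            "continuation in a at delta1 = 12.5",
            sweep=("a", 0.05, 0.45),
        ),
        Preset(
            "fig11", _mp(0.1, 0.1, 4.0, 0.5, 70.0, 1.0, 0.0063),
            "stability boundary lambda_c2 = 0 in the (delta1, delta2) plane",
            alt_eps=(1e-5,),
        ),
    ]
}


def load_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


_PARAM_KEYS = ("a", "kappa", "delta1", "delta2", "delta3", "rho", "eps")


def params_from_mapping(mapping: Dict) -> ModelParams:
    """Build ModelParams from a flat mapping (config file or CLI flags)."""
    kw = {k: float(mapping[k]) for k in _PARAM_KEYS if k in mapping and mapping[k] is not None}
    missing = [k for k in _PARAM_KEYS if k not in kw]
    if missing:
        raise ValueError(f"missing parameters: {', '.join(missing)}")
    return ModelParams(**kw)


def load_config(path) -> Dict:
    """Flat YAML config with keys a, kappa, delta1, ... plus numerics."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat mapping")
    return data


@dataclass
class RunRecord:
    command: str
    config: Dict
    seed: Optional[int]
    version: str
    started: float
    finished: Optional[float] = None
    outputs: Dict[str, object] = field(default_factory=dict)
    stage_hashes: Dict[str, str] = field(default_factory=dict)

    def manifest(self) -> Dict:
        return {
            "command": self.command,
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "started": self.started,
            "finished": self.finished,
            "outputs": {k: str(v) for k, v in self.outputs.items()},
            "stage_hashes": self.stage_hashes,
        }


STAGES = ("states", "singular", "tw", "spectrum", "lambda2", "simulate2d")


def _hash_array(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def run_pipeline(
    params: ModelParams,
    stages: Sequence[str],
    seed: int = 0,
    cache: Optional[Dict] = None,
    sim_options: Optional[Dict] = None,
) -> Tuple[RunRecord, Dict]:
    """Execute analysis stages in dependency order, reusing cached artifacts.

    ``cache`` may be passed between calls to reuse e.g. a solved front.
    Returns (record, cache); the cache holds the stage products under the
    stage names.
    """
    from . import __version__
    from .model_core import classify_regime, steady_states
    from .singular_limit import singular_front
    from .stability import (adjoint_null, lambda_c2, lambda_c2_asymptotic,
                            spectrum)
    from .traveling_wave import measure_gap_width, solve_front

    bad = set(stages) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    # dependency closure, in canonical order
    need = set(stages)
    if "simulate2d" in need or "lambda2" in need or "spectrum" in need:
        need.add("tw")
    if "tw" in need:
        need.add("singular")
    ordered = [s for s in STAGES if s in need]

    cache = cache if cache is not None else {}
    rec = RunRecord(
        command=f"run {'+'.join(ordered)}",
        config=params.as_dict(), seed=seed, version=__version__,
        started=time.time(),
    )
    for stage in ordered:
        if stage in cache:
            rec.outputs[stage] = "cached"
            continue
        if stage == "states":
            cache["states"] = steady_states(params)
            rec.outputs["states"] = [s.label for s in cache["states"]]
        elif stage == "singular":
            cache["singular"] = singular_front(params)
            rec.outputs["singular"] = {
                "regime": cache["singular"].regime.kind.value,
                "w_star": cache["singular"].w_star,
                "c_star": cache["singular"].c_star,
                "gap_width_zeta": cache["singular"].gap_width_zeta,
            }
        elif stage == "tw":
            tw = solve_front(params)
            cache["tw"] = tw
            rec.stage_hashes["tw"] = _hash_array(tw.xi, tw.v, [tw.c])
            wx, wz = measure_gap_width(tw)
            rec.outputs["tw"] = {"c": tw.c, "residual": tw.residual_norm,
                                 "gap_width_xi": wx, "gap_width_zeta": wz}
        elif stage == "spectrum":
            lam, vecs, flags, op = spectrum(cache["tw"], 0.0, count=20,
                                            shift=1e-8)
            cache["spectrum"] = (lam, flags)
            cache["_op"] = op
            rec.outputs["spectrum"] = {
                "translational": float(lam[np.argmax(flags)].real) if flags.any() else None,
                "max_other_real": float(np.max(lam[~flags].real)) if (~flags).any() else None,
            }
        elif stage == "lambda2":
            adj = adjoint_null(cache["tw"], cache.get("_op"))
            lc2 = lambda_c2(cache["tw"], adj)
            try:
                asym = lambda_c2_asymptotic(params)
            except ValueError:
                asym = (None, None)
            cache["lambda2"] = {"numeric": lc2, "asymptotic": asym[0],
                                "sign_asymptotic": asym[1],
                                "eps_scaled": lc2 * params.eps}
            rec.outputs["lambda2"] = cache["lambda2"]
        elif stage == "simulate2d":
            from .simulate2d import evolve, make_initial_condition, mode_growth

            opts = dict(Ny=64, Ly=116.0, noise_amplitude=1e-3, hx=0.1,
                        dt=0.02, T=60.0, snapshot_stride=100)
            opts.update(sim_options or {})
            st = make_initial_condition(
                cache["tw"], Ny=opts["Ny"], Ly=opts["Ly"],
                noise_amplitude=opts["noise_amplitude"], seed=seed,
                hx=opts["hx"],
            )
            st, diags = evolve(st, dt=opts["dt"], T=opts["T"],
                               snapshot_stride=opts["snapshot_stride"])
            cache["simulate2d"] = (st, diags)
            rec.stage_hashes["simulate2d"] = _hash_array(st.V)
            rec.outputs["simulate2d"] = {
                "tau_end": st.tau,
                "mode_growth": mode_growth(diags, [1, 2, 3]),
            }
    rec.finished = time.time()
    return rec, cache
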