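"""Configuration files, run manifests and tabular/JSON writers.

A run is described by a YAML (or JSON) mapping whose keys mirror the model
symbols::

    T: 40.0            # doubling time, minutes
    C: 40.0            # replication time, minutes
    D_post: 20.0       # termination-to-division period, minutes
    k_g: 2.0e-3        # per-second rate constants / scale numerators
    r_g_scale: 2.0e-3  # (accepts the published labels 0.0005/0.002/0.0035)
    k_m_scale: 5.0e-3
    k_p_scale: 1.0e-2
    k_d_scale: 1.0e-3
    r_d: 0.1
    r_m: 3.0e-3
    loci:
      ori: {L: 0.0, copies: 1}
      ter: {L: 1.0, copies: 2}
    seed: 1
    t_end_h: 30.0
    burn_in_h: 0.0
    record_dt_s: 60.0
    init: all_active_empty

An empty file resolves to the default parametrization (T = 40 min, one
copy at *ori*, two at *ter*).  Unknown keys are a hard error; stochastic
commands refuse to run without an explicit seed.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cell_cycle import LocusSpec
from .model_params import RateConstants, label_to_rg
from .stochastic import SimulationConfig

__all__ = ["ConfigError", "load_config", "dump_config", "RunManifest", "write_outputs"]

_RATE_KEYS = ("k_g", "r_g_scale", "k_m_scale", "k_p_scale", "k_d_scale", "r_d", "r_m")
_TOP_KEYS = set(_RATE_KEYS) | {
    "T", "C", "D_post", "loci", "seed", "t_end_h", "burn_in_h",
    "record_dt_s", "init", "rg",
}


class ConfigError(ValueError):
    """Malformed or unknown configuration content (exit code 2 in the CLI)."""


def _num(raw: dict, key: str, default: float) -> float:
    if key not in raw:
        return default
    v = raw[key]
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise ConfigError(f"key {key!r}: expected a number, got {v!r}")
    return float(v)


def load_config(path: str | Path | None) -> SimulationConfig:
    """Resolve a config file into a :class:`SimulationConfig`.

    Missing keys take the default parametrization; ``rg`` is an alias for
    ``r_g_scale`` accepting the published repression labels.  Unknown keys
    raise :class:`ConfigError`.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "rg" in raw and "r_g_scale" in raw:
        raise ConfigError("give either 'rg' or 'r_g_scale', not both")
    rates = {k: _num(raw, k, getattr(RateConstants, k)) for k in _RATE_KEYS}
    if "rg" in raw:
        rates["r_g_scale"] = label_to_rg(_num(raw, "rg", 0.0))
    loci_raw = raw.get("loci", {})
    if not isinstance(loci_raw, dict) or set(loci_raw) - {"ori", "ter"}:
        raise ConfigError("'loci' must be a mapping with keys 'ori' and/or 'ter'")

    def _locus(name: str, default_L: float, default_n: int) -> LocusSpec:
        entry = loci_raw.get(name, {})
        if not isinstance(entry, dict) or set(entry) - {"L", "copies"}:
            raise ConfigError(f"locus {name!r}: expected mapping with keys L, copies")
        return LocusSpec(L=float(entry.get("L", default_L)),
                         n_inserted=int(entry.get("copies", default_n)))

    try:
        return SimulationConfig(
            T=_num(raw, "T", 40.0),
            rc=RateConstants(**rates),
            ori=_locus("ori", 0.0, 1),
            ter=_locus("ter", 1.0, 2),
            t_end_h=_num(raw, "t_end_h", 30.0),
            burn_in_h=_num(raw, "burn_in_h", 0.0),
            record_dt_s=_num(raw, "record_dt_s", 60.0),
            seed=int(raw["seed"]) if "seed" in raw else None,
            init=str(raw.get("init", "all_active_empty")),
            cc_kwargs={k: _num(raw, k, d) for k, d in
                       (("C", 40.0), ("D_post", 20.0))},
        )
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def dump_config(cfg: SimulationConfig) -> dict:
    """Round-trippable plain mapping for a configuration."""
    out = {"T": cfg.T, **{k: getattr(cfg.rc, k) for k in _RATE_KEYS},
           "loci": {"ori": {"L": cfg.ori.L, "copies": cfg.ori.n_inserted},
                    "ter": {"L": cfg.ter.L, "copies": cfg.ter.n_inserted}},
           "t_end_h": cfg.t_end_h, "burn_in_h": cfg.burn_in_h,
           "record_dt_s": cfg.record_dt_s,
           "init": cfg.init if isinstance(cfg.init, str) else "explicit",
           **cfg.cc_kwargs}
    if cfg.seed is not None:
        out["seed"] = cfg.seed
    return out


@dataclass
class RunManifest:
    """Reproducibility sidecar written next to every output file set."""

    command: str
    config: dict
    seeds: list[int] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    version: str = ""
    started_unix: float = field(default_factory=time.time)
    platform: str = field(default_factory=platform.platform)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")
        return path


def write_outputs(results: dict[str, object], out_dir: str | Path,
                  manifest: RunManifest) -> list[Path]:
    """Write result objects (DataFrame → CSV, mapping/scalars → JSON).

    Numeric formatting keeps full precision; the manifest is written
    alongside and lists every file produced.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, obj in results.items():
        if hasattr(obj, "to_csv"):
            p = out_dir / f"{name}.csv"
            obj.to_csv(p, index=False)
        else:
            p = out_dir / f"{name}.json"
            p.write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")
        written.append(p)
    manifest.outputs = [str(p) for p in written]
    written.append(manifest.write(out_dir / "manifest.json"))
    return written


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
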