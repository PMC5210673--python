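"""Shared infrastructure: config files, RNG substreams, manifests, CSV I/O.

Config files are flat TOML key-value documents; unknown keys are rejected
and every value is validated against the model's parameter bounds before a
run starts.  Run manifests are JSON documents recording every resolved
parameter, the master seed, per-replicate substream ids and SHA-256
checksums of the emitted CSVs, so any run can be replayed byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "CONFIG_KEYS",
    "CONFIG_DEFAULTS",
    "load_config",
    "dump_config",
    "validate_config",
    "rng_substream",
    "file_sha256",
    "write_csv",
    "write_manifest",
    "read_manifest",
    "configure_logging",
]

log = logging.getLogger("synchrolang")

# documented defaults; "lambda" is the survival threshold on d_bar
CONFIG_DEFAULTS: dict[str, Any] = {
    "n": 10,
    "k": 4,
    "tau": 40,
    "alpha": 1.0,
    "beta": 0.1,
    "theta": 0.05,
    "eps0": 10.0,
    "lambda": 30.0,
    "steps": 2000,
    "reps": 100,
    "payoff_reps": 1,
    "seed": 0,
}
CONFIG_KEYS = frozenset(CONFIG_DEFAULTS)


def validate_config(params: dict[str, Any]) -> dict[str, Any]:
    """Validate a flat parameter map; fill defaults; reject unknown keys.

    Returns a new dict with every key of ``CONFIG_DEFAULTS`` present and a
    ``_defaulted`` entry listing the keys that were filled from defaults.
    """
    unknown = set(params) - CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; allowed: {sorted(CONFIG_KEYS)}")
    out = dict(CONFIG_DEFAULTS)
    out.update(params)
    defaulted = sorted(CONFIG_KEYS - set(params))

    def bad(key, constraint):
        raise ValueError(f"config key '{key}' = {out[key]!r} violates: {constraint}")

    if not (isinstance(out["n"], int) and out["n"] >= 2):
        bad("n", "integer >= 2")
    if not (isinstance(out["k"], int) and out["k"] >= 1):
        bad("k", "integer >= 1")
    if out["n"] < out["k"] + 1:
        bad("n", f"n >= k+1 (k = {out['k']})")
    if (out["n"] * out["k"]) % 2 != 0:
        bad("n", f"n*k must be even (k = {out['k']})")
    if not (isinstance(out["tau"], int) and out["tau"] >= 0):
        bad("tau", "integer >= 0")
    if out["alpha"] < 0:
        bad("alpha", "alpha >= 0")
    if out["beta"] < 0:
        bad("beta", "beta >= 0")
    if out["theta"] < 0:
        bad("theta", "theta >= 0")
    if not 0.0 <= out["eps0"] <= 180.0:
        bad("eps0", "eps0 in [0, 180]")
    if not 0.0 < out["lambda"] <= 180.0:
        bad("lambda", "lambda in (0, 180]")
    if not (isinstance(out["steps"], int) and out["steps"] >= 0):
        bad("steps", "integer >= 0")
    if not (isinstance(out["reps"], int) and out["reps"] >= 1):
        bad("reps", "integer >= 1")
    if not (isinstance(out["payoff_reps"], int) and out["payoff_reps"] >= 1):
        bad("payoff_reps", "integer >= 1")
    if not isinstance(out["seed"], int):
        bad("seed", "integer")
    out["_defaulted"] = defaulted
    return out


def load_config(path: str | Path) -> dict[str, Any]:
    """Load and validate a flat TOML config file."""
    path = Path(path)
    with path.open("rb") as fh:
        raw = tomllib.load(fh)
    for key, val in raw.items():
        if isinstance(val, (dict, list)):
            raise ValueError(f"config must be flat key-value pairs; key '{key}' is nested")
    return validate_config(raw)


def _toml_scalar(v: Any) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return json.dumps(str(v))


def dump_config(params: dict[str, Any], path: str | Path) -> None:
    """Write a validated parameter map back to flat TOML (round-trippable)."""
    path = Path(path)
    lines = [
        f"{key} = {_toml_scalar(params[key])}" for key in sorted(CONFIG_KEYS) if key in params
    ]
    path.write_text("\n".join(lines) + "\n")


def rng_substream(master_seed: int, stream_id: int) -> np.random.Generator:
    """Independent, replayable substream for (master seed, stream id)."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(stream_id),))
    return np.random.default_rng(ss)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    """Comma-separated, header row, UTF-8, '.' decimal, no index column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, encoding="utf-8")
    return path


def write_manifest(manifest: dict[str, Any], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def configure_logging(verbosity: int = 0) -> None:
    """0 = warnings, 1 = one line per experiment stage, 2 = debug tracing."""
    level = logging.WARNING if verbosity <= 0 else logging.INFO if verbosity == 1 else logging.DEBUG
    logging.basicConfig(format="%(asctime)s %(name)s %(levelname)s %(message)s")
    log.setLevel(level)
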