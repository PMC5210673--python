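"""Reproducible experiment drivers that regenerate the model's headline runs.

Five named protocols, each a deterministic pipeline from a master seed to a
set of CSV tables plus a JSON manifest:

* ``fig1_surface``      — focal-agent best-response noise over an (alpha, beta)
                          cost grid, others fixed at a common level.
* ``fig2_trajectories`` — evolutionary trajectories of group-mean noise for a
                          cheap-precision and an expensive-precision regime.
* ``fig2_phase``        — terminal mean noise over the (alpha, beta) plane.
* ``fig3a_groupsize``   — maximum viable group size versus common noise level.
* ``fig3b_slow``        — iterated best-response descent of a common noise
                          level (the slow route to efficient communication).

Defaults follow the model's reference setting: n = 10, k = 4, tau = 40;
best-response runs average 100 repeats with the others' noise fixed at 30;
evolutionary runs average 40 repeats from eps0 = 10; the slow-dynamics and
group-size runs use alpha = 1, beta = 0.1 and 100 repeats.  Reduced-scale
runs are labelled ``scaled_down`` in the manifest.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .evolution import EvolutionParams, best_response_dynamics, phase_diagram, run_evolution
from .io import file_sha256, log, rng_substream, write_csv, write_manifest, read_manifest
from .payoffs import best_response_noise, max_group_size

__all__ = ["ExperimentSpec", "EXPERIMENT_DEFAULTS", "run_experiment", "rerun_from_manifest"]


EXPERIMENT_DEFAULTS: dict[str, dict[str, Any]] = {
    "fig1_surface": {
        "n": 10, "k": 4, "tau": 40, "eps_others": 30.0, "reps": 100,
        "alpha_grid": [0.01, 0.046, 0.22, 1.0, 4.6, 10.0],
        "beta_grid": [0.01, 0.046, 0.22, 1.0, 4.6, 10.0],
        "eps_grid": list(np.arange(0.0, 181.0, 5.0)),
    },
    "fig2_trajectories": {
        "n": 10, "k": 4, "tau": 40, "alpha": 1.0, "beta_ratios": [0.1, 10.0],
        "eps0": 10.0, "theta": 0.05, "steps": 2000, "payoff_reps": 10, "reps": 40,
    },
    "fig2_phase": {
        "n": 10, "k": 4, "tau": 40,
        "alpha_grid": [0.01, 0.1, 1.0, 10.0], "beta_grid": [0.01, 0.1, 1.0, 10.0],
        "eps0": 10.0, "theta": 0.05, "steps": 2000, "payoff_reps": 10, "reps": 40,
    },
    "fig3a_groupsize": {
        "k": 4, "tau": 40, "lambda": 30.0, "reps": 100,
        "eps_list": [0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0],
        "n_min": 5, "n_max_search": 40,
    },
    "fig3b_slow": {
        "n": 10, "k": 4, "tau": 40, "alpha": 1.0, "beta": 0.1, "reps": 100,
        "eps_start": 60.0, "max_iter": 50,
        "eps_grid": list(np.arange(0.0, 181.0, 5.0)),
    },
}

#: overrides to these keys mark a run as scaled down in the manifest
_SCALE_KEYS = ("reps", "steps", "payoff_reps", "max_iter")


@dataclass(frozen=True)
class ExperimentSpec:
    name: str
    overrides: dict[str, Any] = field(default_factory=dict)
    master_seed: int = 0
    out_dir: str | Path = "results"

    def resolve(self) -> dict[str, Any]:
        if self.name not in EXPERIMENT_DEFAULTS:
            raise ValueError(
                f"unknown experiment {self.name!r}; choose from {sorted(EXPERIMENT_DEFAULTS)}"
            )
        defaults = EXPERIMENT_DEFAULTS[self.name]
        unknown = set(self.overrides) - set(defaults)
        if unknown:
            raise ValueError(
                f"invalid override keys for {self.name}: {sorted(unknown)}; "
                f"allowed: {sorted(defaults)}"
            )
        resolved = {**defaults, **self.overrides}
        return resolved

    def is_scaled_down(self) -> bool:
        defaults = EXPERIMENT_DEFAULTS[self.name]
        return any(
            key in self.overrides and self.overrides[key] < defaults[key]
            for key in _SCALE_KEYS
            if key in defaults
        )


def _run_fig1_surface(p, seed):
    curves, stars = [], []
    stream = 0
    for a in p["alpha_grid"]:
        for b in p["beta_grid"]:
            br = best_response_noise(
                p["eps_others"], float(a), float(b), rng_substream(seed, stream),
                grid=np.asarray(p["eps_grid"], dtype=float),
                n=p["n"], k=p["k"], tau=p["tau"], reps=p["reps"],
            )
            stream += 1
            cur = br.curve.copy()
            cur.insert(0, "beta", float(b))
            cur.insert(0, "alpha", float(a))
            curves.append(cur)
            stars.append((float(a), float(b), br.eps_star))
    return {
        "best_response_curves": pd.concat(curves, ignore_index=True),
        "eps_star": pd.DataFrame(stars, columns=["alpha", "beta", "eps_star"]),
    }, stream


def _run_fig2_trajectories(p, seed):
    mean_rows, final_rows = [], []
    stream = 0
    for ratio in p["beta_ratios"]:
        params = EvolutionParams(
            n=p["n"], k=p["k"], tau=p["tau"], alpha=p["alpha"],
            beta=p["alpha"] * float(ratio), theta=p["theta"], eps0=p["eps0"],
            steps=p["steps"], payoff_reps=p["payoff_reps"],
        )
        mean_acc = np.zeros(p["steps"] + 1)
        for rep in range(p["reps"]):
            traj = run_evolution(params, rng_substream(seed, stream))
            stream += 1
            mean_acc += traj.mean_eps_history
            final_rows.append(
                (
                    float(ratio), rep, traj.final_mean_eps,
                    traj.first_step_reaching(150.0, above=True),
                    traj.first_step_reaching(5.0, above=False),
                    traj.converged(),
                )
            )
        for s, m in enumerate(mean_acc / p["reps"]):
            mean_rows.append((float(ratio), s, m))
    return {
        "trajectories_mean": pd.DataFrame(
            mean_rows, columns=["beta_over_alpha", "step", "mean_eps"]
        ),
        "trajectories_final": pd.DataFrame(
            final_rows,
            columns=[
                "beta_over_alpha", "rep", "final_mean_eps",
                "step_collapse_gt150", "step_fluency_lt5", "converged",
            ],
        ),
    }, stream


def _run_fig2_phase(p, seed):
    params = EvolutionParams(
        n=p["n"], k=p["k"], tau=p["tau"], theta=p["theta"], eps0=p["eps0"],
        steps=p["steps"], payoff_reps=p["payoff_reps"],
    )
    table = phase_diagram(
        p["alpha_grid"], p["beta_grid"], params, rng_substream(seed, 0), reps=p["reps"]
    )
    return {"phase_diagram": table}, 1


def _run_fig3a_groupsize(p, seed):
    tables, summary = [], []
    stream = 0
    for eps in p["eps_list"]:
        res = max_group_size(
            float(eps), p["lambda"], rng_substream(seed, stream),
            k=p["k"], tau=p["tau"],
            n_range=range(p["n_min"], p["n_max_search"] + 1), reps=p["reps"],
        )
        stream += 1
        tab = res.table.copy()
        tab.insert(0, "eps_common", float(eps))
        tables.append(tab)
        summary.append((float(eps), p["lambda"], res.n_max, res.censored))
    return {
        "group_size_table": pd.concat(tables, ignore_index=True),
        "n_max_summary": pd.DataFrame(
            summary, columns=["eps_common", "lambda", "n_max", "censored"]
        ),
    }, stream


def _run_fig3b_slow(p, seed):
    seq = best_response_dynamics(
        p["eps_start"], rng_substream(seed, 0), alpha=p["alpha"], beta=p["beta"],
        n=p["n"], k=p["k"], tau=p["tau"], reps=p["reps"],
        grid=np.asarray(p["eps_grid"], dtype=float), max_iter=p["max_iter"],
    )
    return {
        "best_response_path": pd.DataFrame(
            {"iteration": np.arange(len(seq)), "eps_common": seq}
        )
    }, 1


_RUNNERS = {
    "fig1_surface": _run_fig1_surface,
    "fig2_trajectories": _run_fig2_trajectories,
    "fig2_phase": _run_fig2_phase,
    "fig3a_groupsize": _run_fig3a_groupsize,
    "fig3b_slow": _run_fig3b_slow,
}


def run_experiment(spec: ExperimentSpec) -> dict[str, Any]:
    """Execute a named experiment; write CSV tables and a JSON manifest.

    Identical specs (name, overrides, master seed) produce byte-identical
    CSV tables.  Returns a dict with the manifest and the table paths.
    """
    resolved = spec.resolve()
    out_dir = Path(spec.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("experiment %s starting (seed=%d)", spec.name, spec.master_seed)

    tables, n_streams = _RUNNERS[spec.name](resolved, spec.master_seed)

    paths: dict[str, str] = {}
    checksums: dict[str, str] = {}
    for name, frame in tables.items():
        path = write_csv(frame, out_dir / f"{spec.name}_{name}.csv")
        paths[name] = str(path)
        checksums[path.name] = file_sha256(path)

    manifest = {
        "experiment": spec.name,
        "version": __version__,
        "master_seed": spec.master_seed,
        "substreams_used": n_streams,
        "parameters": {k: _jsonable(v) for k, v in resolved.items()},
        "overridden_keys": sorted(spec.overrides),
        "scaled_down": spec.is_scaled_down(),
        "generated_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "output_checksums": checksums,
    }
    manifest_path = write_manifest(manifest, out_dir / f"{spec.name}_manifest.json")
    log.info("experiment %s wrote %d tables to %s", spec.name, len(paths), out_dir)
    return {"manifest": str(manifest_path), "tables": paths}


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, list):
        return [_jsonable(x) for x in v]
    return v


def rerun_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> dict[str, Any]:
    """Replay an experiment from its manifest; reproduces the CSVs byte-for-byte."""
    man = read_manifest(manifest_path)
    name = man["experiment"]
    defaults = EXPERIMENT_DEFAULTS[name]
    overrides = {k: man["parameters"][k] for k in man.get("overridden_keys", []) if k in defaults}
    spec = ExperimentSpec(
        name=name, overrides=overrides, master_seed=man["master_seed"], out_dir=out_dir
    )
    return run_experiment(spec)
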