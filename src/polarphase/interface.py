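"""Configuration-driven entry point: reduce -> simulate -> analyze.

A run is described by one YAML/JSON config with a ``task`` key.  Outputs are
written atomically (temp file + rename) and every run emits a JSON metadata
file echoing the config and recording the seed, so identical config + seed
reproduces byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import phase_dynamics as pd_mod
from . import reduction, ring_rd, tissue_geometry
from .models import make_model

__all__ = ["RunConfig", "ConfigError", "run", "load_config"]

log = logging.getLogger("polarphase")

_TASKS = ("reduce", "simulate-rd", "simulate-phase", "analyze")


class ConfigError(ValueError):
    """Configuration failed schema validation."""


@dataclass
class RunConfig:
    task: str
    raw: dict
    path: Optional[str] = None

    @property
    def outdir(self) -> Path:
        return Path(self.raw.get("output", {}).get("dir", "."))


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            raw = yaml.safe_load(fh)
        else:
            raw = json.load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    task = raw.get("task")
    if task not in _TASKS:
        raise ConfigError(f"field 'task' must be one of {_TASKS}, got {task!r}")
    return RunConfig(task=task, raw=raw, path=str(path))


def _atomic_write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _atomic_write_df(path: Path, df: pd.DataFrame) -> None:
    _atomic_write(path, df.to_csv(index=False, float_format="%.12g"))


def _require(cfg: dict, key: str, context: str) -> object:
    if key not in cfg:
        raise ConfigError(f"missing field '{key}' in {context} block")
    return cfg[key]


def _build_model(cfg: dict):
    block = _require(cfg, "model", "top-level")
    name = _require(block, "name", "model")
    return make_model(name, **block.get("params", {}))


def _build_tissue(cfg: dict):
    block = _require(cfg, "tissue", "top-level")
    return tissue_geometry.build_tissue(block)


def _coupling_from_doc(doc: dict):
    return {float(w): reduction.PhaseCoupling.from_dict(g) for w, g in doc["couplings"].items()}


def _write_meta(cfg: RunConfig, outdir: Path, seed, extra: dict, t0: float) -> None:
    meta = {
        "task": cfg.task,
        "config": cfg.raw,
        "seed": seed,
        "wall_time_s": round(time.time() - t0, 3),
    }
    meta.update(extra)
    _atomic_write(outdir / "run_meta.json", json.dumps(meta, indent=2, sort_keys=True))


def _task_reduce(cfg: RunConfig) -> list:
    raw = cfg.raw
    model = _build_model(raw)
    num = raw.get("numerics", {})
    n_theta = int(num.get("n_theta", 256))
    K = int(num.get("K", 8))
    kind = raw.get("coupling_kind", "difference")
    widths = raw.get("widths")
    if widths is None:
        delta = raw.get("tissue", {}).get("delta", np.pi / 3)
        shape = tissue_geometry.hex_shape(delta)
        widths = sorted({round(float(w), 12) for w in shape.widths})
    cell = reduction.reduce_cell(model, n_theta=n_theta)
    fd = reduction.fourier_coefficients(cell, K=K)
    doc = {
        "model": {"name": model.name, "params": model.params},
        "n_theta": n_theta,
        "K": K,
        "kind": kind,
        "residual": cell.residual,
        "u": list(fd.u),
        "z": list(fd.z),
        "couplings": {
            str(w): reduction.gamma_from_fourier(fd, w, kind=kind).to_dict() for w in widths
        },
    }
    out = cfg.outdir / raw.get("output", {}).get("reduction", "reduction.json")
    _atomic_write(out, json.dumps(doc, indent=2))
    return [out]


def _task_simulate_rd(cfg: RunConfig) -> list:
    raw = cfg.raw
    model = _build_model(raw)
    tissue = _build_tissue(raw)
    num = raw.get("numerics", {})
    n_theta = int(num.get("n_theta", 256))
    dt = float(_require(num, "dt", "numerics"))
    T = float(_require(num, "T", "numerics"))
    stride = int(num.get("sample_every", 100))
    eps = float(raw.get("eps", 0.0))
    stoch = raw.get("stochastic", {})
    seed = stoch.get("seed")
    noise = None
    if stoch.get("nu"):
        if seed is None:
            raise ConfigError("missing field 'seed' in stochastic block (required when nu > 0)")
        noise = ring_rd.NoiseSpec(nu=stoch["nu"], seed=int(seed))
    signal = None
    if stoch.get("eps_e"):
        signal = ring_rd.SignalSpec(eps_e=float(stoch["eps_e"]), psi=float(stoch.get("psi", 0.0)))

    phi0 = raw.get("initial_phases", [0.0] * tissue.n_cells)
    if len(phi0) != tissue.n_cells:
        raise ConfigError("initial_phases length does not match the tissue")
    cell = reduction.find_steady_state(model, n_theta=n_theta)
    from ._spectral import rotate

    init = np.stack([rotate(cell.X_S, p) for p in phi0])
    traj = ring_rd.integrate_tissue_rd(
        tissue, model, eps, init, T, dt,
        noise=noise, signal=signal,
        coupling=raw.get("coupling_kind", "difference"),
        sample_every=stride,
    )
    phases = traj.phases()
    amps = traj.first_harmonic_amplitude()
    rows = []
    for s, t in enumerate(traj.times):
        for i in range(tissue.n_cells):
            rows.append((t, i, phases[s, i], amps[s, i]))
    df = pd.DataFrame(rows, columns=["time", "cell_id", "phase", "C"])
    outdir = cfg.outdir
    files = [outdir / raw.get("output", {}).get("phases", "phases_rd.csv")]
    _atomic_write_df(files[0], df)
    fields_name = raw.get("output", {}).get("fields")
    if fields_name:
        try:
            import h5py
        except ImportError as exc:  # pragma: no cover
            raise ConfigError("field output requires h5py") from exc
        path = outdir / fields_name
        path.parent.mkdir(parents=True, exist_ok=True)
        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=traj.times)
            fh.create_dataset("fields", data=traj.fields)
        files.append(path)
    return files


def _phase_spec_from_config(raw: dict):
    tissue = _build_tissue(raw)
    coup_cfg = _require(raw, "coupling", "top-level")
    if "reduction_file" in coup_cfg:
        with open(coup_cfg["reduction_file"]) as fh:
            doc = json.load(fh)
        coupling = _coupling_from_doc(doc)
    elif coup_cfg.get("kind") == "gle_closed_form":
        coupling = pd_mod.coupling_table(
            tissue, lambda w: pd_mod.gle_coupling(w, coup_cfg.get("variant", "difference"))
        )
    elif coup_cfg.get("kind") == "harmonic":
        coupling = pd_mod.harmonic_coupling(
            a=coup_cfg.get("a", 0.0), b=coup_cfg.get("b", 0.0),
            b_prime=coup_cfg.get("b_prime", 0.0), c=coup_cfg.get("c", 0.0),
        )
    else:
        raise ConfigError("coupling block needs 'reduction_file' or kind in {gle_closed_form, harmonic}")
    stoch = raw.get("stochastic", {})
    signal = None
    if stoch.get("eps_e"):
        signal = pd_mod.PhaseSignal(
            eps_e=float(stoch["eps_e"]),
            psi=float(stoch.get("psi", 0.0)),
            amplitude=float(stoch.get("signal_amplitude", 1.0)),
        )
    nu = float(stoch.get("nu", 0.0))
    return pd_mod.PhaseModelSpec(
        tissue, coupling, eps=float(raw.get("eps", 1.0)), signal=signal, noise=nu
    )


def _task_simulate_phase(cfg: RunConfig) -> list:
    raw = cfg.raw
    spec = _phase_spec_from_config(raw)
    num = raw.get("numerics", {})
    T = float(_require(num, "T", "numerics"))
    dt = float(num.get("dt", 0.01))
    stoch = raw.get("stochastic", {})
    seed = stoch.get("seed")
    if spec.noise > 0 and seed is None:
        raise ConfigError("missing field 'seed' in stochastic block (required when nu > 0)")
    init_cfg = raw.get("initial_phases", {"kind": "constant", "phi0": 0.0})
    if isinstance(init_cfg, list):
        init = pd_mod.PhaseState(np.asarray(init_cfg, dtype=float))
    else:
        kw = {k: v for k, v in init_cfg.items() if k not in ("kind", "seed")}
        init = pd_mod.initial_phases(init_cfg["kind"], spec.n_cells, seed=init_cfg.get("seed"), **kw)
    n_samples = int(num.get("n_samples", 201))
    traj = pd_mod.integrate_phase(
        spec, init, T, dt=dt,
        seed=int(seed) if seed is not None else None,
        t_eval=np.linspace(0.0, T, n_samples),
    )
    rows = []
    for s, t in enumerate(traj.times):
        for i in range(spec.n_cells):
            rows.append((t, i, traj.phi[s, i]))
    df = pd.DataFrame(rows, columns=["time", "cell_id", "phase"])
    op = traj.order_parameters()
    df_op = pd.DataFrame({"time": traj.times, "Q": op[:, 0], "Phi": op[:, 1]})
    outdir = cfg.outdir
    files = [
        outdir / raw.get("output", {}).get("phases", "phases.csv"),
        outdir / raw.get("output", {}).get("order_parameter", "order_parameter.csv"),
    ]
    _atomic_write_df(files[0], df)
    _atomic_write_df(files[1], df_op)
    return files


def _task_analyze(cfg: RunConfig) -> list:
    raw = cfg.raw
    out = {}
    if "delta" in raw:
        out["lambda"] = pd_mod.elongation_coefficient(float(raw["delta"]))
    if "two_cell" in raw:
        blk = raw["two_cell"]
        out["two_cell"] = two = []
        for fp in pd_mod.two_cell_analysis(
            float(blk["a"]), float(blk["b"]), float(blk["c"]), eps=float(blk.get("eps", 1.0))
        ):
            two.append(
                {
                    "fixed_point": list(fp["fixed_point"]),
                    "eigenvalues": list(fp["eigenvalues"]),
                    "stability": fp["stability"],
                }
            )
    if "heterogeneity" in raw:
        blk = raw["heterogeneity"]
        out["heterogeneity_rate"] = pd_mod.axial_asymmetry_rates(
            alpha=float(blk["alpha"]), b=float(blk["b"]), c=float(blk["c"])
        )["heterogeneity_rate"]
    if "tissue" in raw and "coupling" in raw:
        spec = _phase_spec_from_config(raw)
        R, eta_bar = pd_mod.in_phase_effective_field(spec.tissue, spec.coupling)
        out["effective_field"] = {"R": list(R), "eta_bar": list(eta_bar)}
    if not out:
        raise ConfigError("analyze task needs at least one of: delta, two_cell, heterogeneity, tissue+coupling")
    path = cfg.outdir / cfg.raw.get("output", {}).get("analysis", "analysis.json")
    _atomic_write(path, json.dumps(out, indent=2))
    return [path]


def run(config) -> list:
    """Execute a run configuration; returns the list of written files."""
    t0 = time.time()
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    task_fn = {
        "reduce": _task_reduce,
        "simulate-rd": _task_simulate_rd,
        "simulate-phase": _task_simulate_phase,
        "analyze": _task_analyze,
    }[cfg.task]
    log.info("task %s starting", cfg.task)
    files = task_fn(cfg)
    seed = cfg.raw.get("stochastic", {}).get("seed")
    _write_meta(cfg, cfg.outdir, seed, {"outputs": [str(f) for f in files]}, t0)
    log.info("task %s wrote %d file(s)", cfg.task, len(files))
    return files
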