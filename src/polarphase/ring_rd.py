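"""Reaction-diffusion dynamics on per-cell periodic rings with contact coupling.

Each cell carries concentration profiles on a uniform periodic grid of its
boundary angle.  Neighbouring cells interact only on their shared contact
surfaces, through the facing-point map: the point ``theta_i`` of cell i
touches ``theta_j* = eta_ji - (theta_i - eta_ij)`` of cell j (the two
counter-clockwise parametrised boundaries run antiparallel along the shared
surface).

Time stepping splits the dynamics: reaction, coupling, signal and noise are
advanced by an explicit (Euler / Euler-Maruyama) step, then diffusion is
applied exactly in Fourier space via the factor ``exp(-D k^2 dt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np

from ._spectral import TWO_PI, circular_grid, trig_eval, trig_interp_matrix, wrap
from .models import ReactionModel
from .tissue_geometry import TissueGraph

__all__ = [
    "RingField",
    "NoiseSpec",
    "SignalSpec",
    "RDTrajectory",
    "facing_point",
    "contact_indicator",
    "coupling_term",
    "integrate_tissue_rd",
    "extract_phase",
    "UndefinedPhaseError",
]

MIN_GRID = 64


class UndefinedPhaseError(ValueError):
    """First circular harmonic too small to define a polarity direction."""


@dataclass
class RingField:
    """Per-cell concentration profiles on the uniform periodic theta grid."""

    values: np.ndarray  # (n_species, n_theta)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (n_species, n_theta)")
        if self.values.shape[1] < MIN_GRID:
            raise ValueError(f"n_theta must be >= {MIN_GRID}")

    @property
    def n_theta(self) -> int:
        return self.values.shape[1]

    @property
    def grid(self) -> np.ndarray:
        return circular_grid(self.n_theta)


@dataclass(frozen=True)
class NoiseSpec:
    """Space-time white noise intensities, one per species, and a seed."""

    nu: Sequence[float]
    seed: int

    def __post_init__(self):
        if np.any(np.asarray(self.nu) < 0):
            raise ValueError("noise intensities must be >= 0")


@dataclass(frozen=True)
class SignalSpec:
    """External unimodal signal eps_e * (cos(psi(t) - theta), 0, ...)."""

    eps_e: float
    psi: Union[float, Callable[[float], float]]

    def direction(self, t: float) -> float:
        return self.psi(t) if callable(self.psi) else self.psi


def facing_point(eta_ij: float, eta_ji: float, theta_i, d_ij: Optional[float] = None):
    """Point of cell j's boundary facing ``theta_i`` of cell i, in [0, 2pi)."""
    theta_i = np.asarray(theta_i, dtype=float)
    offset = wrap(theta_i - eta_ij)
    if d_ij is not None and np.any(np.abs(offset) > d_ij / 2 + 1e-12):
        raise ValueError("theta_i lies outside the contact surface")
    out = (eta_ji - offset) % TWO_PI
    if theta_i.ndim == 0:
        return float(out)
    return out


def contact_indicator(eta_ij: float, d_ij: float, theta):
    """1 on the contact surface |wrap(theta - eta_ij)| < d_ij/2, else 0."""
    if not 0.0 < d_ij < TWO_PI:
        raise ValueError("d_ij must lie in (0, 2pi)")
    theta = np.asarray(theta, dtype=float)
    out = (np.abs(wrap(theta - eta_ij)) < d_ij / 2).astype(float)
    if theta.ndim == 0:
        return float(out)
    return out


def coupling_term(kind: str, edge, U_i: np.ndarray, U_j: np.ndarray) -> np.ndarray:
    """Contact interaction H_ij on the grid; acts on the U component only.

    ``kind`` selects ``U_i - U_j(theta*)`` ("difference") or ``-U_j(theta*)``
    ("pure_inhibition"); the result is zero off the contact surface and its
    V row is identically zero.
    """
    U_i = np.asarray(U_i, dtype=float)
    U_j = np.asarray(U_j, dtype=float)
    if U_i.shape != U_j.shape:
        raise ValueError("mismatched grids")
    n = U_i.shape[-1]
    theta = circular_grid(n)
    mask = contact_indicator(edge.eta, edge.d, theta).astype(bool)
    H = np.zeros((2, n))
    theta_star = facing_point(edge.eta, edge.eta_rev, theta[mask])
    Uj_star = trig_eval(U_j, theta_star)
    if kind == "difference":
        H[0, mask] = U_i[mask] - Uj_star
    elif kind == "pure_inhibition":
        H[0, mask] = -Uj_star
    else:
        raise ValueError(f"unknown coupling kind {kind!r}")
    return H


@dataclass
class RDTrajectory:
    """Sampled tissue states: ``fields[s]`` has shape (n_cells, n_species, n_theta)."""

    times: np.ndarray
    fields: np.ndarray
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def phases(self, tol_C: float = 1e-6) -> np.ndarray:
        """Extracted polarity phase per (sample, cell)."""
        n_samp, n_cells = self.fields.shape[:2]
        out = np.empty((n_samp, n_cells))
        for s in range(n_samp):
            for i in range(n_cells):
                out[s, i] = extract_phase(self.fields[s, i], tol_C=tol_C)
        return out

    def first_harmonic_amplitude(self) -> np.ndarray:
        n = self.fields.shape[-1]
        phase_factor = np.exp(-1j * circular_grid(n))
        return np.abs(np.mean(self.fields[:, :, 0, :] * phase_factor, axis=-1))


def _edge_tables(tissue: TissueGraph, n: int):
    """Precompute, per directed edge, the masked indices and the spectral
    interpolation matrix evaluating the neighbour's field at facing points."""
    theta = circular_grid(n)
    tables = []
    for e in tissue.edges:
        mask = contact_indicator(e.eta, e.d, theta).astype(bool)
        idx = np.nonzero(mask)[0]
        theta_star = facing_point(e.eta, e.eta_rev, theta[idx])
        M = trig_interp_matrix(n, theta_star)
        tables.append((e.i, e.j, e.alpha, idx, M))
    return tables


def integrate_tissue_rd(
    tissue: TissueGraph,
    model: ReactionModel,
    eps: float,
    init: np.ndarray,
    T: float,
    dt: float,
    noise: Optional[NoiseSpec] = None,
    signal: Optional[SignalSpec] = None,
    coupling: str = "difference",
    sample_every: int = 100,
    eps_warn_threshold: float = 0.1,
) -> RDTrajectory:
    """Integrate the coupled tissue model and return sampled states.

    ``init`` has shape (n_cells, n_species, n_theta).  Deterministic runs are
    bit-reproducible for a fixed grid and dt; stochastic runs are reproducible
    given ``noise.seed``.
    """
    import warnings

    X = np.array(init, dtype=float)
    if X.ndim != 3 or X.shape[0] != tissue.n_cells or X.shape[1] != model.n_species:
        raise ValueError("init must be (n_cells, n_species, n_theta)")
    n = X.shape[2]
    if n < MIN_GRID:
        raise ValueError(f"n_theta must be >= {MIN_GRID}")
    if abs(eps) > eps_warn_threshold:
        warnings.warn("coupling strength eps is large; the weak-coupling regime is eps << 1")

    n_steps = int(round(T / dt))
    theta = circular_grid(n)
    k = np.fft.rfftfreq(n, d=1.0 / n)
    decay = np.exp(-model.diffusion[None, :, None] * (k**2)[None, None, :] * dt)
    tables = _edge_tables(tissue, n) if eps != 0.0 else []

    rng = None
    noise_scale = None
    if noise is not None and np.any(np.asarray(noise.nu) > 0):
        rng = np.random.default_rng(noise.seed)
        dtheta = TWO_PI / n
        noise_scale = np.sqrt(np.asarray(noise.nu, dtype=float) * dt / dtheta)[None, :, None]

    samples = [X.copy()]
    sample_times = [0.0]
    t = 0.0
    for step in range(1, n_steps + 1):
        drift = np.moveaxis(model.reaction(np.moveaxis(X, 1, 0)), 0, 1)
        if eps != 0.0:
            for i, j, alpha, idx, M in tables:
                Uj_star = M @ X[j, 0]
                if coupling == "difference":
                    h = X[i, 0, idx] - Uj_star
                elif coupling == "pure_inhibition":
                    h = -Uj_star
                else:
                    raise ValueError(f"unknown coupling kind {coupling!r}")
                drift[i, 0, idx] += eps * (1.0 + alpha) * h
        if signal is not None and signal.eps_e != 0.0:
            drift[:, 0, :] += signal.eps_e * np.cos(signal.direction(t) - theta)[None, :]
        X = X + dt * drift
        if rng is not None:
            X = X + noise_scale * rng.standard_normal(X.shape)
        X = np.fft.irfft(np.fft.rfft(X, axis=-1) * decay, n=n, axis=-1)
        t = step * dt
        if step % 50 == 0 and not np.all(np.isfinite(X)):
            raise RuntimeError(f"instability detected at t = {t:g} (non-finite values)")
        if step % sample_every == 0 or step == n_steps:
            samples.append(X.copy())
            sample_times.append(t)
    if not np.all(np.isfinite(X)):
        raise RuntimeError("instability detected (non-finite values)")
    return RDTrajectory(
        times=np.array(sample_times),
        fields=np.array(samples),
        seed=noise.seed if noise is not None else None,
        meta={"dt": dt, "eps": eps, "coupling": coupling, "model": model.name},
    )


def extract_phase(field, tol_C: float = 1e-6) -> float:
    """Polarity phase from the first circular harmonic of the U profile.

    Solves ``(1/2pi) int U e^{-i theta} = C e^{-i phi}`` and returns phi in
    (-pi, pi]; raises :class:`UndefinedPhaseError` when C <= tol_C.
    """
    values = field.values if isinstance(field, RingField) else np.asarray(field, dtype=float)
    U = values[0] if values.ndim == 2 else values
    n = U.shape[-1]
    Uhat = np.mean(U * np.exp(-1j * circular_grid(n)))
    C = abs(Uhat)
    if C <= tol_C:
        raise UndefinedPhaseError(f"first harmonic amplitude {C:.3e} <= {tol_C:.3e}")
    return wrap(-np.angle(Uhat))
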