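"""Phase reduction of a single-cell ring pattern.

Pipeline: relax the uncoupled cell to its steady unimodal pattern and polish
it with Newton iterations (translational mode pinned), compute the Goldstone
mode and the adjoint zero eigenfunction of the linearised operator, project
onto circular harmonics, and assemble the pairwise phase-coupling function
Gamma_ij as a list of sinusoidal terms ``A * sin(p*eta - q*phi_i - r*phi_j)``.

``gamma_direct`` evaluates the defining inner product of Gamma_ij by
quadrature and serves as an independent oracle for the Fourier assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.linalg

from ._spectral import (
    TWO_PI,
    circular_grid,
    cosine_coefficient,
    rotate,
    second_derivative_matrix,
    sine_coefficient,
    spectral_derivative,
    trig_eval,
    wrap,
)
from .models import ReactionModel

__all__ = [
    "PatternLostError",
    "DegenerateNullSpaceError",
    "ReducedCell",
    "FourierData",
    "PhaseCoupling",
    "find_steady_state",
    "adjoint_zero_mode",
    "adjoint_zero_mode_relaxation",
    "reduce_cell",
    "fourier_coefficients",
    "shape_coefficients",
    "gamma_from_fourier",
    "gamma_direct",
    "linear_operator_matrix",
    "default_pattern_init",
    "inner_product",
]


class PatternLostError(RuntimeError):
    """Relaxation converged to a homogeneous state: no polarity pattern."""


class DegenerateNullSpaceError(RuntimeError):
    """Discretised operator has a null space of dimension != 1."""


def inner_product(A: np.ndarray, B: np.ndarray) -> float:
    """<A, B> = integral over [0, 2pi) of A . B (periodic trapezoid rule)."""
    n = A.shape[-1]
    return float(np.sum(A * B) * TWO_PI / n)


@dataclass
class ReducedCell:
    """Steady pattern with its zero modes, aligned so U^S peaks at theta = 0."""

    model: ReactionModel
    X_S: np.ndarray  # (n_species, n_theta)
    Y0: np.ndarray  # Goldstone mode, -dX^S/dtheta
    residual: float
    Z0: Optional[np.ndarray] = None  # adjoint zero mode, <Z0, Y0> = 1

    @property
    def n_theta(self) -> int:
        return self.X_S.shape[-1]

    @property
    def grid(self) -> np.ndarray:
        return circular_grid(self.n_theta)


def default_pattern_init(model: ReactionModel, n_theta: int, phi0: float = 0.0) -> np.ndarray:
    """Initial condition for pattern formation.

    Generic rule: homogeneous fixed point plus an amplitude-0.1
    ``cos(theta - phi0)`` perturbation on U.  The GLE keeps ``V = 0``
    invariant under that rule, so it is seeded on the rotating family
    ``0.1 (cos, sin)`` instead.
    """
    from .models import homogeneous_fixed_point

    theta = circular_grid(n_theta)
    if model.name == "gle":
        return 0.1 * np.stack([np.cos(theta - phi0), np.sin(theta - phi0)])
    fp = homogeneous_fixed_point(model)
    X = np.repeat(fp[:, None], n_theta, axis=1)
    X[0] += 0.1 * np.cos(theta - phi0)
    return X


def _steady_residual(model: ReactionModel, X: np.ndarray) -> np.ndarray:
    return model.reaction(X) + model.diffusion[:, None] * spectral_derivative(X, order=2)


def linear_operator_matrix(model: ReactionModel, X: np.ndarray) -> np.ndarray:
    """Dense discretisation of ``J + D d^2/dtheta^2`` about profile X.

    State vectors are ordered species-major: (U_0..U_{n-1}, V_0..V_{n-1}, ...).
    """
    s, n = X.shape
    J = model.jacobian(X)  # (s, s, n)
    D2 = second_derivative_matrix(n)
    blocks = []
    for a in range(s):
        row = []
        for b in range(s):
            blk = np.diag(J[a, b])
            if a == b:
                blk = blk + model.diffusion[a] * D2
            row.append(blk)
        blocks.append(row)
    return np.block(blocks)


_DEFAULT_DT = {"gle": 0.05, "activator_inhibitor": 1.0}


def _refine_peak(U: np.ndarray) -> float:
    """Sub-grid location of the maximum of the trig interpolant of U."""
    n = U.shape[-1]
    fine = np.linspace(0.0, TWO_PI, 16 * n, endpoint=False)
    phi = fine[np.argmax(trig_eval(U, fine))]
    dU = spectral_derivative(U)
    d2U = spectral_derivative(U, order=2)
    for _ in range(4):  # Newton on U'(phi) = 0
        g = trig_eval(dU, phi)
        h = trig_eval(d2U, phi)
        if h >= 0:
            break
        phi -= g / h
    return wrap(phi)


def find_steady_state(
    model: ReactionModel,
    n_theta: int = 256,
    init: Optional[np.ndarray] = None,
    dt: Optional[float] = None,
    t_max: float = 2e4,
    relax_tol: float = 1e-5,
    residual_tol: float = 1e-8,
    pattern_tol: float = 1e-3,
    max_newton: int = 30,
) -> ReducedCell:
    """Relax to the steady unimodal pattern and align its peak to theta = 0.

    Relaxation uses the splitting integrator (exact spectral diffusion,
    explicit reaction); a Newton polish with the translational mode pinned
    then drives the residual to round-off.
    """
    if init is None:
        X = default_pattern_init(model, n_theta)
    else:
        X = np.array(init, dtype=float)
    if dt is None:
        dt = _DEFAULT_DT.get(model.name, 0.05)
    n = X.shape[-1]
    k = np.fft.rfftfreq(n, d=1.0 / n)
    decay = np.exp(-model.diffusion[:, None] * (k**2)[None, :] * dt)
    theta = circular_grid(n)

    t = 0.0
    check_every = max(1, int(round(10.0 / dt)))
    step = 0
    while t < t_max:
        X_new = X + dt * model.reaction(X)
        X_new = np.fft.irfft(np.fft.rfft(X_new, axis=-1) * decay, n=n, axis=-1)
        t += dt
        step += 1
        if step % check_every == 0:
            if not np.all(np.isfinite(X_new)):
                raise RuntimeError("relaxation diverged (non-finite values)")
            # splitting fixed points carry an O(dt) PDE residual, so stop on
            # the scheme's own rate of change instead
            rate = np.max(np.abs(X_new - X)) / dt
            if rate < relax_tol:
                X = X_new
                break
        X = X_new
    amp = abs(np.mean(X[0] * np.exp(-1j * theta)))
    if amp < pattern_tol:
        raise PatternLostError(
            f"first-harmonic amplitude {amp:.2e} < {pattern_tol:.2e}: "
            "converged to a homogeneous state"
        )

    # Newton polish with a bordered system pinning the translation direction.
    for _ in range(max_newton):
        r = _steady_residual(model, X)
        res = np.max(np.abs(r))
        if res < 1e-12:
            break
        A = linear_operator_matrix(model, X)
        y = (-spectral_derivative(X)).ravel()
        m = A.shape[0]
        bordered = np.zeros((m + 1, m + 1))
        bordered[:m, :m] = A
        bordered[:m, m] = y
        bordered[m, :m] = y
        rhs = np.concatenate([-r.ravel(), [0.0]])
        delta = np.linalg.solve(bordered, rhs)[:m]
        X = X + delta.reshape(X.shape)
    res = np.max(np.abs(_steady_residual(model, X)))
    if res > residual_tol:
        raise RuntimeError(f"Newton polish stalled at residual {res:.2e}")

    phi = _refine_peak(X[0])
    X = rotate(X, -phi)  # U^S(theta) <- U^S(theta + phi): peak moves to 0
    Y0 = -spectral_derivative(X)
    res = np.max(np.abs(_steady_residual(model, X)))
    return ReducedCell(model=model, X_S=X, Y0=Y0, residual=float(res))


def adjoint_zero_mode(
    model: ReactionModel,
    cell: ReducedCell,
    tol: float = 1e-6,
) -> np.ndarray:
    """Null vector of the adjoint of the discretised linear operator.

    Found from the SVD of the transposed operator matrix and normalised so
    that ``<Z0, Y0> = 1``.  The null space must be one-dimensional at the
    given tolerance (relative to the largest singular value).
    """
    A = linear_operator_matrix(model, cell.X_S)
    U_, s, Vt = scipy.linalg.svd(A.T)
    scale = s[0]
    if s[-1] > tol * scale:
        raise DegenerateNullSpaceError(f"no null vector: smallest sigma {s[-1]:.2e}")
    if s[-2] < tol * scale:
        raise DegenerateNullSpaceError("null space dimension > 1 at tolerance")
    Z = Vt[-1].reshape(cell.X_S.shape)
    ip = inner_product(Z, cell.Y0)
    if abs(ip) < 1e-12:
        raise DegenerateNullSpaceError("null vector orthogonal to the Goldstone mode")
    Z = Z / ip
    cell.Z0 = Z
    return Z


def adjoint_zero_mode_relaxation(
    model: ReactionModel,
    cell: ReducedCell,
    dt: float = 50.0,
    n_steps: int = 400,
    tol: float = 1e-10,
) -> np.ndarray:
    """Cross-check route: relax ``dZ/dt = L^dagger Z`` to its fixed direction."""
    A = linear_operator_matrix(model, cell.X_S)
    P = scipy.linalg.expm(A.T * dt)
    theta = circular_grid(cell.n_theta)
    Z = np.stack([np.sin(theta), -np.cos(theta)] + [np.zeros_like(theta)] * (cell.X_S.shape[0] - 2))
    Z = Z / inner_product(Z, cell.Y0)
    for _ in range(n_steps):
        Z_new = (P @ Z.ravel()).reshape(Z.shape)
        Z_new = Z_new / inner_product(Z_new, cell.Y0)
        if np.max(np.abs(Z_new - Z)) < tol:
            Z = Z_new
            break
        Z = Z_new
    return Z


def reduce_cell(model: ReactionModel, n_theta: int = 256, **kwargs) -> ReducedCell:
    """Full single-cell reduction: steady state plus adjoint zero mode."""
    cell = find_steady_state(model, n_theta=n_theta, **kwargs)
    adjoint_zero_mode(model, cell)
    return cell


@dataclass(frozen=True)
class FourierData:
    """Two-sided circular-harmonic coefficients of U^S and Z0^(U).

    Conventions: ``U^S(theta) = sum_k u_k cos(k theta)`` and
    ``Z0^(U)(theta) = sum_k -z_k sin(k theta)`` with the sums over all
    integers k and the symmetries ``u_{-k} = u_k``, ``z_{-k} = -z_k``;
    stored one-sided as ``u[0..K]`` and ``z[1..K]`` (``z[0] = 0``) via
    ``u_k = (1/2pi) int U^S cos(k theta)`` for k >= 0 and
    ``z_k = -(1/2pi) int Z0^(U) sin(k theta)`` for k >= 1.
    """

    u: np.ndarray
    z: np.ndarray
    K: int
    asymmetry: float = 0.0

    def u_at(self, k: int) -> float:
        k = abs(k)
        return float(self.u[k]) if k <= self.K else 0.0

    def z_at(self, k: int) -> float:
        sign = -1.0 if k < 0 else 1.0
        k = abs(k)
        return sign * float(self.z[k]) if k <= self.K else 0.0


def fourier_coefficients(cell: ReducedCell, K: int = 8, asym_tol: float = 1e-3) -> FourierData:
    """Project the aligned steady pattern and adjoint mode onto harmonics."""
    if cell.Z0 is None:
        raise ValueError("cell has no adjoint mode; call adjoint_zero_mode first")
    U = cell.X_S[0]
    ZU = cell.Z0[0]
    U_reflected = np.roll(U[::-1], 1)  # U(-theta) on the grid
    asym = 0.5 * float(np.max(np.abs(U - U_reflected)))
    if asym > asym_tol:
        raise RuntimeError(
            f"steady profile asymmetry {asym:.2e} exceeds {asym_tol:.2e}: alignment failed"
        )
    u = np.array([cosine_coefficient(U, k) for k in range(K + 1)])
    z = np.array([0.0] + [-sine_coefficient(ZU, k) for k in range(1, K + 1)])
    return FourierData(u=u, z=z, K=K, asymmetry=asym)


def shape_coefficients(d: float, K: int) -> np.ndarray:
    """Cosine coefficients of the centred contact indicator, s_0..s_K.

    ``s_0 = d/(2pi)`` and ``s_k = sin(k d/2)/(k pi)`` for k >= 1; the
    two-sided extension is even (``s_{-k} = s_k``).
    """
    if not 0.0 < d < TWO_PI:
        raise ValueError("d must lie in (0, 2pi)")
    k = np.arange(1, K + 1)
    return np.concatenate([[d / TWO_PI], np.sin(k * d / 2.0) / (k * np.pi)])


def _s_at(s: np.ndarray, k: int) -> float:
    return float(s[abs(k)])


@dataclass
class PhaseCoupling:
    """Gamma_ij as a canonical list of terms ``A sin(p*eta - q*phi_i - r*phi_j)``.

    Keys (p, q, r) are unique after folding via sin(-x) = -sin(x) so that
    p > 0, or p = 0 and q > 0, or p = q = 0 and r > 0.
    """

    terms: Dict[Tuple[int, int, int], float] = field(default_factory=dict)

    @property
    def a(self) -> float:
        """Coefficient of sin(phi_j - phi_i)."""
        return self.term(0, 1, -1)

    @property
    def b(self) -> float:
        """Coefficient of sin 2(eta - phi_i)."""
        return self.term(2, 2, 0)

    @property
    def b_prime(self) -> float:
        """Coefficient of sin(eta - phi_i)."""
        return self.term(1, 1, 0)

    @property
    def c(self) -> float:
        """Coefficient of sin(2 eta - phi_i - phi_j)."""
        return self.term(2, 1, 1)

    def term(self, p: int, q: int, r: int) -> float:
        return self.terms.get((p, q, r), 0.0)

    def evaluate(self, eta, phi_i, phi_j):
        out = 0.0
        for (p, q, r), amp in self.terms.items():
            out = out + amp * np.sin(p * np.asarray(eta) - q * np.asarray(phi_i) - r * np.asarray(phi_j))
        return out

    def to_dict(self) -> dict:
        return {
            "terms": [
                {"p": p, "q": q, "r": r, "amplitude": amp}
                for (p, q, r), amp in sorted(self.terms.items())
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhaseCoupling":
        return cls({(t["p"], t["q"], t["r"]): t["amplitude"] for t in d["terms"]})


def _canonical_key(p: int, q: int, r: int) -> Tuple[Tuple[int, int, int], float]:
    if (p, q, r) == (0, 0, 0):
        return (0, 0, 0), 0.0
    if p < 0 or (p == 0 and (q < 0 or (q == 0 and r < 0))):
        return (-p, -q, -r), -1.0
    return (p, q, r), 1.0


def gamma_from_fourier(
    fd: FourierData,
    d: float,
    kind: str = "difference",
    amp_tol: float = 1e-4,
) -> PhaseCoupling:
    """Assemble Gamma_ij from circular-harmonic coefficients.

    The "difference" coupling ``S (U_i - U_j(theta*))`` contributes a cross
    term (from the neighbour, carrying the parity factor (-1)^l) and a self
    term depending on phi_i only; "pure_inhibition" keeps the cross term
    alone.  Shape coefficients appear with index |l - k| <= 2K, so the
    indicator itself is never truncated.
    """
    if kind not in ("difference", "pure_inhibition"):
        raise ValueError(f"unknown coupling kind {kind!r}")
    K = fd.K
    s = shape_coefficients(d, 2 * K + 1)
    acc: Dict[Tuple[int, int, int], float] = {}

    def add(p: int, q: int, r: int, amp: float) -> None:
        key, sign = _canonical_key(p, q, r)
        if sign == 0.0:
            return
        acc[key] = acc.get(key, 0.0) + sign * amp

    for kk in range(-K, K + 1):
        zk = fd.z_at(kk)
        if zk == 0.0:
            continue
        for ll in range(-K, K + 1):
            ul = fd.u_at(ll)
            if ul == 0.0:
                continue
            cross = TWO_PI * zk * ul * ((-1.0) ** ll) * _s_at(s, ll - kk)
            add(kk + ll, kk, ll, cross)
            if kind == "difference":
                self_amp = -TWO_PI * zk * ul * _s_at(s, -kk - ll)
                add(kk + ll, kk + ll, 0, self_amp)

    terms = {key: amp for key, amp in acc.items() if abs(amp) >= amp_tol}
    return PhaseCoupling(terms)


def gamma_direct(
    cell: ReducedCell,
    edge,
    kind: str = "difference",
    grid_n: int = 64,
    quad_n: int = 400,
) -> Tuple[np.ndarray, np.ndarray]:
    """Brute-force table of Gamma_ij(phi_i, phi_j) by quadrature.

    Evaluates ``<Z0(theta - phi_i), H_ij^S(theta)>`` with Gauss-Legendre
    nodes on the exact contact arc, using the trigonometric interpolants of
    the steady pattern and the adjoint mode.  Returns ``(phi_grid, table)``
    with ``table[p, q] = Gamma(phi_grid[p], phi_grid[q])``.
    """
    if cell.Z0 is None:
        raise ValueError("cell has no adjoint mode; call adjoint_zero_mode first")
    if kind not in ("difference", "pure_inhibition"):
        raise ValueError(f"unknown coupling kind {kind!r}")
    eta, eta_rev, d = edge.eta, edge.eta_rev, edge.d
    nodes, weights = np.polynomial.legendre.leggauss(quad_n)
    theta = eta + 0.5 * d * nodes
    w = 0.5 * d * weights
    theta_star = eta_rev - (theta - eta)

    phi = circular_grid(grid_n)
    Z = trig_eval(cell.Z0[0], theta[:, None] - phi[None, :])  # (quad_n, grid_n)
    U_self = trig_eval(cell.X_S[0], theta[:, None] - phi[None, :])
    U_cross = trig_eval(cell.X_S[0], theta_star[:, None] - phi[None, :])
    cross_part = (Z * w[:, None]).T @ U_cross  # (grid_n_i, grid_n_j)
    table = -cross_part
    if kind == "difference":
        self_part = np.sum(w[:, None] * Z * U_self, axis=0)  # depends on phi_i only
        table = table + self_part[:, None]
    return phi, table
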