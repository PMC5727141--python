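"""Reduced phase model on a tissue graph.

Each cell carries one polarity angle.  The drift is
``eps * sum_j (1 + alpha_ij) Gamma_ij(phi_i, phi_j)`` plus an optional
external-signal term and scalar white noise.  For couplings restricted to
the a / b / b' / c sinusoidal family the dynamics is a gradient system; the
corresponding potential and its Boltzmann stationary density are provided,
together with the closed-form analyses of two-cell stability, the in-phase
effective field and the elongation / heterogeneity rate coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

from ._spectral import TWO_PI, wrap
from .reduction import PhaseCoupling
from .tissue_geometry import TissueGraph

__all__ = [
    "PhaseState",
    "PhaseSignal",
    "PhaseModelSpec",
    "PhaseTrajectory",
    "phase_rhs",
    "integrate_phase",
    "sample_stationary",
    "order_parameter",
    "potential",
    "stationary_density",
    "DensityTable",
    "two_cell_analysis",
    "in_phase_effective_field",
    "axial_asymmetry_rates",
    "elongation_coefficient",
    "noise_variance",
    "initial_phases",
    "gle_coupling",
    "harmonic_coupling",
    "coupling_table",
    "NonGradientCouplingError",
]

_GRADIENT_KEYS = {(0, 1, -1): "a", (2, 2, 0): "b", (1, 1, 0): "b_prime", (2, 1, 1): "c"}


class NonGradientCouplingError(ValueError):
    """Potential requested for a coupling outside the a/b/b'/c family."""


@dataclass
class PhaseState:
    """Polarity angles of all cells at one instant."""

    phi: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phases must be finite")


@dataclass(frozen=True)
class PhaseSignal:
    """Reduced external signal ``eps_e * amplitude * sin(psi(t) - phi_i)``."""

    eps_e: float
    psi: Union[float, Callable[[float], float]]
    amplitude: float = 1.0

    def direction(self, t: float) -> float:
        return self.psi(t) if callable(self.psi) else self.psi


def gle_signal_amplitude(D0: float) -> float:
    """Closed-form signal amplitude 1/(2 sqrt(1 - D0)) for the GLE."""
    return 1.0 / (2.0 * math.sqrt(1.0 - D0))


def gle_coupling(d: float, kind: str = "difference") -> PhaseCoupling:
    """Closed-form GLE coupling: a = b = sin(d)/(4pi), c = d/(4pi).

    The pure-inhibition variant has b' = 0 (the mean of U^S vanishes), so it
    equals the difference coupling with b = 0.
    """
    a = math.sin(d) / (4.0 * math.pi)
    c = d / (4.0 * math.pi)
    terms = {(0, 1, -1): a, (2, 1, 1): c}
    if kind == "difference":
        terms[(2, 2, 0)] = a
    elif kind != "pure_inhibition":
        raise ValueError(f"unknown coupling kind {kind!r}")
    return PhaseCoupling(terms)


def harmonic_coupling(a: float = 0.0, b: float = 0.0, b_prime: float = 0.0, c: float = 0.0) -> PhaseCoupling:
    """Coupling from explicit a / b / b' / c coefficients (zeros dropped)."""
    terms = {}
    for key, val in [((0, 1, -1), a), ((2, 2, 0), b), ((1, 1, 0), b_prime), ((2, 1, 1), c)]:
        if val != 0.0:
            terms[key] = float(val)
    return PhaseCoupling(terms)


def coupling_table(tissue: TissueGraph, builder: Callable[[float], PhaseCoupling]) -> Dict[float, PhaseCoupling]:
    """Coupling per distinct edge width, from a width -> coupling builder."""
    return {w: builder(w) for w in tissue.widths}


@dataclass
class PhaseModelSpec:
    """Tissue, per-width coupling, and optional signal / noise."""

    tissue: TissueGraph
    coupling: Union[PhaseCoupling, Dict[float, PhaseCoupling]]
    eps: float = 1.0
    signal: Optional[PhaseSignal] = None
    noise: float = 0.0

    def __post_init__(self):
        if self.noise < 0:
            raise ValueError("noise intensity must be >= 0")
        self.coupling_for_width = self._make_lookup()
        self._compiled = None

    def _make_lookup(self):
        if isinstance(self.coupling, PhaseCoupling):
            return lambda w: self.coupling
        table = {round(float(w), 12): g for w, g in self.coupling.items()}

        def lookup(w: float) -> PhaseCoupling:
            key = round(float(w), 12)
            if key not in table:
                raise KeyError(f"no coupling for edge width {w!r}")
            return table[key]

        for w in self.tissue.widths:
            lookup(w)
        return lookup

    @property
    def n_cells(self) -> int:
        return self.tissue.n_cells

    def compiled(self) -> "_CompiledTerms":
        if self._compiled is None:
            self._compiled = _compile(self)
        return self._compiled


@dataclass
class _CompiledTerms:
    """Flattened (edge, term) arrays for vectorised drift evaluation."""

    i_idx: np.ndarray
    amp: np.ndarray  # eps * (1 + alpha) * A, premultiplied
    arg_eta: np.ndarray  # p * eta
    q: np.ndarray
    r: np.ndarray
    j_idx: np.ndarray
    n_cells: int
    scatter: object = None  # sparse (n_terms, n_cells) accumulator

    def __post_init__(self):
        from scipy.sparse import csr_matrix

        n_terms = self.i_idx.size
        if n_terms:
            self.scatter = csr_matrix(
                (np.ones(n_terms), (np.arange(n_terms), self.i_idx)),
                shape=(n_terms, self.n_cells),
            )


def _compile(spec: PhaseModelSpec) -> _CompiledTerms:
    i_l, j_l, amp_l, eta_l, q_l, r_l = [], [], [], [], [], []
    for e in spec.tissue.edges:
        gamma = spec.coupling_for_width(e.d)
        for (p, q, r), A in gamma.terms.items():
            i_l.append(e.i)
            j_l.append(e.j)
            amp_l.append(spec.eps * (1.0 + e.alpha) * A)
            eta_l.append(p * e.eta)
            q_l.append(q)
            r_l.append(r)
    return _CompiledTerms(
        i_idx=np.array(i_l, dtype=np.intp),
        amp=np.array(amp_l),
        arg_eta=np.array(eta_l),
        q=np.array(q_l, dtype=float),
        r=np.array(r_l, dtype=float),
        j_idx=np.array(j_l, dtype=np.intp),
        n_cells=spec.n_cells,
    )


def phase_rhs(state: Union[PhaseState, np.ndarray], spec: PhaseModelSpec, t: float = 0.0) -> np.ndarray:
    """Deterministic drift of the phase model.

    Accepts a :class:`PhaseState` or a phase array of shape ``(..., N)``;
    leading axes broadcast over independent replicas.
    """
    phi = state.phi if isinstance(state, PhaseState) else np.asarray(state, dtype=float)
    if isinstance(state, PhaseState):
        t = state.t
    ct = spec.compiled()
    rate = np.zeros(phi.shape)
    if ct.amp.size:
        args = ct.arg_eta - ct.q * phi[..., ct.i_idx] - ct.r * phi[..., ct.j_idx]
        contrib = ct.amp * np.sin(args)
        if phi.ndim == 1:
            rate = np.bincount(ct.i_idx, weights=contrib, minlength=ct.n_cells).astype(float)
        else:
            flat = contrib.reshape(-1, contrib.shape[-1])
            rate = np.asarray(flat @ ct.scatter).reshape(phi.shape)
    if spec.signal is not None and spec.signal.eps_e != 0.0:
        rate = rate + spec.signal.eps_e * spec.signal.amplitude * np.sin(spec.signal.direction(t) - phi)
    return rate


@dataclass
class PhaseTrajectory:
    times: np.ndarray
    phi: np.ndarray  # (n_samples, n_cells), wrapped to (-pi, pi]
    seed: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def order_parameters(self) -> np.ndarray:
        """(Q, Phi) per sample, shape (n_samples, 2)."""
        return np.array([order_parameter(p) for p in self.phi])


def integrate_phase(
    spec: PhaseModelSpec,
    init: Union[PhaseState, np.ndarray],
    T: float,
    dt: float = 0.01,
    seed: Optional[int] = None,
    t_eval: Optional[np.ndarray] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> PhaseTrajectory:
    """Integrate the phase model over [0, T].

    Deterministic runs use adaptive Runge-Kutta (RK45); stochastic runs
    (``spec.noise > 0``) use Euler-Maruyama with step ``dt`` and require a
    seed.  Output phases are wrapped to (-pi, pi].
    """
    phi0 = np.array(init.phi if isinstance(init, PhaseState) else init, dtype=float)
    if phi0.shape != (spec.n_cells,):
        raise ValueError("init length does not match the tissue")
    if T <= 0:
        raise ValueError("T must be positive")
    if t_eval is None:
        t_eval = np.linspace(0.0, T, 201)
    t_eval = np.asarray(t_eval, dtype=float)

    if spec.noise > 0:
        if seed is None:
            raise ValueError("stochastic integration requires a seed")
        rng = np.random.default_rng(seed)
        n_steps = int(round(T / dt))
        sigma = math.sqrt(spec.noise * dt)
        phi = phi0.copy()
        out = np.empty((t_eval.size, phi0.size))
        next_sample = 0
        t = 0.0
        if t_eval[0] <= 0.0:
            out[0] = phi
            next_sample = 1
        for step in range(1, n_steps + 1):
            phi = phi + dt * phase_rhs(phi, spec, t) + sigma * rng.standard_normal(phi.shape)
            t = step * dt
            while next_sample < t_eval.size and t_eval[next_sample] <= t + 1e-12:
                out[next_sample] = phi
                next_sample += 1
        out[next_sample:] = phi
        if not np.all(np.isfinite(out)):
            raise RuntimeError("non-finite phases during stochastic integration")
        return PhaseTrajectory(t_eval.copy(), wrap(out), seed=seed, meta={"dt": dt, "scheme": "euler-maruyama"})

    sol = solve_ivp(
        lambda t, y: phase_rhs(y, spec, t),
        (0.0, T),
        phi0,
        method="RK45",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"phase integration failed: {sol.message}")
    return PhaseTrajectory(sol.t.copy(), wrap(sol.y.T), seed=None, meta={"scheme": "rk45", "rtol": rtol})


def sample_stationary(
    spec: PhaseModelSpec,
    n_traj: int,
    T: float,
    dt: float,
    seed: int,
    burn_fraction: float = 0.2,
    sample_stride: int = 100,
    init_low: float = -math.pi,
    init_high: float = math.pi,
) -> np.ndarray:
    """Euler-Maruyama ensemble sampler of the stationary phase distribution.

    Runs ``n_traj`` independent replicas from uniform initial phases,
    discards the burn-in fraction and returns wrapped samples of shape
    ``(n_samples, n_cells)``.
    """
    if spec.noise <= 0:
        raise ValueError("sampling the stationary density requires noise > 0")
    rng = np.random.default_rng(seed)
    N = spec.n_cells
    phi = rng.uniform(init_low, init_high, size=(n_traj, N))
    n_steps = int(round(T / dt))
    burn_steps = int(round(burn_fraction * n_steps))
    sigma = math.sqrt(spec.noise * dt)
    chunks = []
    for step in range(1, n_steps + 1):
        phi = phi + dt * phase_rhs(phi, spec, step * dt) + sigma * rng.standard_normal(phi.shape)
        if step > burn_steps and step % sample_stride == 0:
            chunks.append(wrap(phi).copy())
    return np.concatenate(chunks, axis=0)


def order_parameter(phi: Union[PhaseState, np.ndarray], require_direction: bool = True):
    """Modulus Q and argument Phi of the population-mean phasor.

    When Q < 1e-12 the mean direction is undefined: raises by default, or
    returns ``(Q, nan)`` with ``require_direction=False``.
    """
    p = phi.phi if isinstance(phi, PhaseState) else np.asarray(phi, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one cell")
    mean = np.mean(np.exp(1j * p))
    Q = abs(mean)
    if Q < 1e-12:
        if require_direction:
            raise ValueError("order parameter modulus ~ 0: mean direction undefined")
        return Q, float("nan")
    return Q, float(np.angle(mean))


def _gradient_coeffs(spec: PhaseModelSpec, width: float):
    gamma = spec.coupling_for_width(width)
    extra = set(gamma.terms) - set(_GRADIENT_KEYS)
    if extra:
        raise NonGradientCouplingError(
            f"coupling has non-gradient terms {sorted(extra)}; "
            "the potential is defined only for the a/b/b'/c family"
        )
    return gamma.a, gamma.b, gamma.b_prime, gamma.c


def potential(state: Union[PhaseState, np.ndarray], spec: PhaseModelSpec, t: float = 0.0) -> Union[float, np.ndarray]:
    """Potential of the gradient system (drift = -dH/dphi).

    Supports phase arrays of shape ``(..., N)``.  Refuses couplings with
    terms outside the a/b/b'/c family.
    """
    phi = state.phi if isinstance(state, PhaseState) else np.asarray(state, dtype=float)
    if isinstance(state, PhaseState):
        t = state.t
    H = np.zeros(phi.shape[:-1])
    for e in spec.tissue.edges:
        a, b, bp, c = _gradient_coeffs(spec, e.d)
        pi_, pj = phi[..., e.i], phi[..., e.j]
        contrib = (
            a * np.cos(pj - pi_)
            + b * np.cos(2.0 * (e.eta - pi_))
            + 2.0 * bp * np.cos(e.eta - pi_)
            + c * np.cos(2.0 * e.eta - pi_ - pj)
        )
        H = H - 0.5 * spec.eps * (1.0 + e.alpha) * contrib
    if spec.signal is not None and spec.signal.eps_e != 0.0:
        psi = spec.signal.direction(t)
        H = H - spec.signal.eps_e * spec.signal.amplitude * np.sum(np.cos(psi - phi), axis=-1)
    if phi.ndim == 1:
        return float(H)
    return H


@dataclass
class DensityTable:
    """Boltzmann stationary density on a phase grid, with 1-D marginals."""

    phi: np.ndarray  # (grid_n,) cell-centred grid on [0, 2pi)
    joint: np.ndarray  # (grid_n,) * n_cells
    marginals: np.ndarray  # (n_cells, grid_n), each integrates to 1


def stationary_density(spec: PhaseModelSpec, nu: float, grid_n: int = 120) -> DensityTable:
    """Normalised density ``P propto exp(-2 H / nu)`` by quadrature (N <= 3)."""
    N = spec.n_cells
    if N > 3:
        raise ValueError("stationary density quadrature is guarded to N <= 3")
    if nu <= 0:
        raise ValueError("nu must be positive")
    dphi = TWO_PI / grid_n
    axis = dphi * (np.arange(grid_n) + 0.5)
    mesh = np.meshgrid(*([axis] * N), indexing="ij")
    phis = np.stack(mesh, axis=-1)
    H = potential(phis, spec)
    H = H - np.min(H)
    P = np.exp(-2.0 * H / nu)
    P /= np.sum(P) * dphi**N
    marginals = np.empty((N, grid_n))
    for i in range(N):
        other = tuple(ax for ax in range(N) if ax != i)
        marginals[i] = np.sum(P, axis=other) * dphi ** (N - 1)
    return DensityTable(phi=axis, joint=P, marginals=marginals)


def two_cell_analysis(a: float, b: float, c: float, eps: float = 1.0):
    """Fixed points of a straight pair (eta = 0 / pi) with stability labels.

    At the in-phase states ``phi* in {0, pi, +-pi/2}`` the sum and difference
    coordinates decouple, with eigenvalues ``-2 eps (b + c) cos(2 phi*)`` and
    ``-2 eps (a + b cos(2 phi*))``.
    """
    results = []
    for phi_star in (0.0, math.pi, math.pi / 2.0, -math.pi / 2.0):
        cos2 = math.cos(2.0 * phi_star)
        lam_sum = -2.0 * eps * (b + c) * cos2
        lam_diff = -2.0 * eps * (a + b * cos2)
        eigs = (lam_sum, lam_diff)
        if max(eigs) < 0:
            label = "stable"
        elif max(eigs) > 0:
            label = "unstable"
        else:
            label = "neutral"
        results.append(
            {
                "fixed_point": (phi_star, phi_star),
                "eigenvalues": eigs,
                "stability": label,
            }
        )
    return results


def in_phase_effective_field(tissue: TissueGraph, coupling: Union[PhaseCoupling, Dict[float, PhaseCoupling]]):
    """Per-cell net geometric drive (R_i, eta_bar_i) under the in-phase assumption.

    ``R_i e^{2 i eta_bar_i} = sum_j (1 + alpha_ij)(b_ij + c_ij) e^{2 i eta_ij}``;
    eta_bar is reported in (-pi/2, pi/2] (defined modulo pi).
    """
    spec = PhaseModelSpec(tissue, coupling, eps=1.0)
    R = np.zeros(tissue.n_cells)
    eta_bar = np.zeros(tissue.n_cells)
    acc = np.zeros(tissue.n_cells, dtype=complex)
    for e in tissue.edges:
        gamma = spec.coupling_for_width(e.d)
        acc[e.i] += (1.0 + e.alpha) * (gamma.b + gamma.c) * np.exp(2j * e.eta)
    R = np.abs(acc)
    eta_bar = np.angle(acc) / 2.0
    eta_bar = np.where(eta_bar <= -np.pi / 2, eta_bar + np.pi, eta_bar)
    eta_bar = np.where(eta_bar > np.pi / 2, eta_bar - np.pi, eta_bar)
    return R, eta_bar


def elongation_coefficient(delta: float) -> float:
    """Closed-form elongation coefficient lambda(delta).

    Positive lambda stabilises polarity along the delta-edge axis
    (phi in {0, pi}); negative lambda stabilises phi = +-pi/2; lambda = 0 at
    the regular hexagon delta = pi/3.
    """
    if not 0.0 < delta < math.pi:
        raise ValueError("delta must lie in (0, pi)")
    return (
        math.sin(delta) / (4.0 * math.pi)
        + delta / (4.0 * math.pi)
        - 2.0
        * (math.sin((math.pi - delta) / 2.0) / (4.0 * math.pi) + (math.pi - delta) / (8.0 * math.pi))
        * math.sin(delta / 2.0)
    )


def axial_asymmetry_rates(
    delta: Optional[float] = None,
    alpha: Optional[float] = None,
    b: Optional[float] = None,
    c: Optional[float] = None,
) -> dict:
    """Rate coefficients of the axial symmetry-breaking drives.

    Returns ``lambda`` for uniform elongation (given ``delta``) and/or the
    heterogeneity rate coefficient ``2 alpha (b + c)`` (given alpha, b, c);
    both act through a ``-2 eps <coef> sin(2 phi)`` drift on the in-phase
    state.
    """
    out = {}
    if delta is not None:
        out["lambda"] = elongation_coefficient(delta)
    if alpha is not None:
        if b is None or c is None:
            raise ValueError("heterogeneity rate requires b and c")
        out["heterogeneity_rate"] = 2.0 * alpha * (b + c)
    if not out:
        raise ValueError("provide delta and/or (alpha, b, c)")
    return out


def noise_variance(nu_m: Sequence[float], Z0: np.ndarray) -> float:
    """Reduced scalar noise intensity ``nu = sum_m nu_m int (Z0^(m))^2``."""
    nu_m = np.asarray(nu_m, dtype=float)
    Z0 = np.asarray(Z0, dtype=float)
    if nu_m.shape[0] != Z0.shape[0]:
        raise ValueError("one intensity per species required")
    n = Z0.shape[-1]
    integrals = np.sum(Z0**2, axis=-1) * TWO_PI / n
    return float(np.dot(nu_m, integrals))


def initial_phases(kind: str, N: int, seed: Optional[int] = None, **kwargs) -> PhaseState:
    """Seeded initial phases: ``uniform(lo, hi)`` or ``constant(phi0)``."""
    if kind == "uniform":
        lo, hi = kwargs["lo"], kwargs["hi"]
        if lo >= hi:
            raise ValueError("need lo < hi")
        if seed is None:
            raise ValueError("uniform initial phases require a seed")
        rng = np.random.default_rng(seed)
        return PhaseState(rng.uniform(lo, hi, size=N))
    if kind == "constant":
        return PhaseState(np.full(N, float(kwargs["phi0"])))
    raise ValueError(f"unknown initial-phase kind {kind!r}")
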