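"""Built-in reaction kinetics for single-cell ring dynamics.

Two models are provided: the real Ginzburg-Landau equation (``gle``) and a
two-species activator-inhibitor model (``activator_inhibitor``).  Custom
models can be registered through :func:`register_model` with the same
contract: a reaction function, an (optional) analytic Jacobian and a vector
of per-species diffusivities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional

import numpy as np

__all__ = [
    "DomainError",
    "ReactionModel",
    "make_model",
    "register_model",
    "finite_difference_jacobian",
]


class DomainError(ValueError):
    """State outside the admissible domain of a reaction model."""


@dataclass(frozen=True)
class ReactionModel:
    """Reaction kinetics F, Jacobian dF/dX and diagonal diffusivities.

    ``reaction`` and ``jacobian`` act on arrays of shape ``(n_species, ...)``
    and return shapes ``(n_species, ...)`` and ``(n_species, n_species, ...)``
    respectively; trailing axes broadcast over grid points / cells.
    """

    name: str
    n_species: int
    diffusion: np.ndarray
    params: Dict[str, float]
    _reaction: Callable = field(repr=False)
    _jacobian: Callable = field(repr=False)

    def reaction(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._reaction(X, self.params)

    def jacobian(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._jacobian(X, self.params)


def _gle_reaction(X, p):
    U, V = X[0], X[1]
    r2 = U * U + V * V
    return np.stack([U - r2 * U, V - r2 * V])


def _gle_jacobian(X, p):
    U, V = X[0], X[1]
    one = np.ones_like(U)
    return np.stack(
        [
            np.stack([one - 3 * U * U - V * V, -2 * U * V]),
            np.stack([-2 * U * V, one - U * U - 3 * V * V]),
        ]
    )


def _check_ai_domain(U, V):
    if np.any(V <= 0.0):
        raise DomainError("activator-inhibitor model requires V > 0")
    if np.any(U < 0.0):
        raise DomainError("activator-inhibitor model requires U >= 0")


def _ai_reaction(X, p):
    U, V = X[0], X[1]
    _check_ai_domain(U, V)
    sat = 1.0 + p["kappa"] * U * U
    FU = p["rho_U"] * U * U / (sat * V) - p["mu_U"] * U + p["sigma_U"]
    FV = p["rho_V"] * U * U - p["mu_V"] * V
    return np.stack([FU, FV])


def _ai_jacobian(X, p):
    U, V = X[0], X[1]
    _check_ai_domain(U, V)
    sat = 1.0 + p["kappa"] * U * U
    dFU_dU = 2.0 * p["rho_U"] * U / (sat * sat * V) - p["mu_U"] * np.ones_like(U)
    dFU_dV = -p["rho_U"] * U * U / (sat * V * V)
    dFV_dU = 2.0 * p["rho_V"] * U
    dFV_dV = -p["mu_V"] * np.ones_like(V)
    return np.stack([np.stack([dFU_dU, dFU_dV]), np.stack([dFV_dU, dFV_dV])])


def finite_difference_jacobian(reaction: Callable, params: Dict[str, float], step: float = 1e-6):
    """Build a central finite-difference Jacobian for a reaction function."""

    def jac(X, p):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        cols = []
        for j in range(n):
            h = step * max(1.0, float(np.max(np.abs(X[j]), initial=0.0)))
            Xp, Xm = X.copy(), X.copy()
            Xp[j] = Xp[j] + h
            Xm[j] = Xm[j] - h
            cols.append((reaction(Xp, p) - reaction(Xm, p)) / (2.0 * h))
        return np.stack(cols, axis=1)

    return jac


_GLE_DEFAULTS = {"D0": 0.3}
_AI_DEFAULTS = {
    "rho_U": 0.01,
    "rho_V": 0.02,
    "mu_U": 0.01,
    "mu_V": 0.02,
    "sigma_U": 0.0,
    "kappa": 0.0,
    "D_U": 0.005,
    "D_V": 0.2,
}

_REGISTRY: Dict[str, Callable[..., ReactionModel]] = {}


def register_model(
    name: str,
    reaction: Callable,
    diffusion,
    n_species: int,
    jacobian: Optional[Callable] = None,
    defaults: Optional[Dict[str, float]] = None,
) -> None:
    """Register a user model under ``name`` for :func:`make_model`."""
    defaults = dict(defaults or {})
    if jacobian is None:
        jacobian = finite_difference_jacobian(reaction, defaults)

    def factory(**params):
        p = dict(defaults)
        p.update(params)
        D = np.asarray(diffusion, dtype=float)
        _validate_diffusion(D, n_species)
        return ReactionModel(name, n_species, D, p, reaction, jacobian)

    _REGISTRY[name] = factory


def _validate_diffusion(D: np.ndarray, n_species: int) -> None:
    if D.shape != (n_species,):
        raise ValueError(f"diffusion must have shape ({n_species},)")
    if np.any(D <= 0.0):
        raise ValueError("diffusivities must be positive")


def make_model(name: str, **params) -> ReactionModel:
    """Create a built-in (or registered) reaction model.

    Parameters override the documented defaults (GLE: ``D0=0.3``;
    activator-inhibitor: ``rho_U=0.01, rho_V=0.02, mu_U=0.01, mu_V=0.02,
    sigma_U=0, kappa=0, D_U=0.005, D_V=0.2``).
    """
    if name == "gle":
        p = dict(_GLE_DEFAULTS)
        unknown = set(params) - set(p)
        if unknown:
            raise ValueError(f"unknown GLE parameters: {sorted(unknown)}")
        p.update(params)
        D = np.array([p["D0"], p["D0"]], dtype=float)
        _validate_diffusion(D, 2)
        return ReactionModel("gle", 2, D, p, _gle_reaction, _gle_jacobian)
    if name == "activator_inhibitor":
        p = dict(_AI_DEFAULTS)
        unknown = set(params) - set(p)
        if unknown:
            raise ValueError(f"unknown activator-inhibitor parameters: {sorted(unknown)}")
        p.update(params)
        D = np.array([p["D_U"], p["D_V"]], dtype=float)
        _validate_diffusion(D, 2)
        return ReactionModel("activator_inhibitor", 2, D, p, _ai_reaction, _ai_jacobian)
    if name in _REGISTRY:
        return _REGISTRY[name](**params)
    raise ValueError(f"unknown model {name!r}")


def homogeneous_fixed_point(model: ReactionModel) -> np.ndarray:
    """A homogeneous kinetic fixed point used to seed pattern formation."""
    if model.name == "gle":
        return np.zeros(2)
    if model.name == "activator_inhibitor":
        p = model.params
        if p["kappa"] != 0.0 or p["sigma_U"] != 0.0:
            raise ValueError("closed-form fixed point requires kappa = sigma_U = 0")
        U = p["rho_U"] * p["mu_V"] / (p["rho_V"] * p["mu_U"])
        V = p["rho_V"] * U * U / p["mu_V"]
        return np.array([U, V])
    raise ValueError(f"no homogeneous fixed point known for {model.name!r}")
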