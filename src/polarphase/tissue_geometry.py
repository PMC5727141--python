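"""Hexagonal cell shapes and tissue contact graphs.

Cells are regular or elongated hexagons with perimeter 2*pi.  A shape is
described purely by the arc widths of its six edges and the positions of the
edge midpoints in the cell's own boundary coordinate ``theta``; tissues are
directed graphs whose edges carry the contact-surface midpoint ``eta_ij``,
width ``d_ij`` and a dimensionless coupling heterogeneity ``alpha_ij``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._spectral import TWO_PI, wrap

__all__ = [
    "HexCellShape",
    "TissueEdge",
    "TissueGraph",
    "hex_shape",
    "build_tissue",
    "chain",
    "hex_sheet",
    "winding",
    "apply_heterogeneity",
]


@dataclass(frozen=True)
class HexCellShape:
    """Arc widths and midpoints of a (possibly elongated) hexagon.

    The two edges of width ``delta`` face theta = 0 and pi; the four oblique
    edges have width ``delta_prime = (pi - delta)/2``.
    """

    delta: float

    def __post_init__(self):
        if not 0.0 < self.delta < np.pi:
            raise ValueError("delta must lie in (0, pi)")

    @property
    def delta_prime(self) -> float:
        return (np.pi - self.delta) / 2.0

    @property
    def widths(self) -> np.ndarray:
        d, dp = self.delta, self.delta_prime
        return np.array([d, dp, dp, d, dp, dp])

    @property
    def midpoints(self) -> np.ndarray:
        d = self.delta
        return np.array(
            [
                0.0,
                (np.pi + d) / 4.0,
                (3.0 * np.pi - d) / 4.0,
                np.pi,
                -(3.0 * np.pi - d) / 4.0,
                -(np.pi + d) / 4.0,
            ]
        )


def hex_shape(delta: float) -> HexCellShape:
    """Hexagonal cell shape with axis-facing edge width ``delta``."""
    return HexCellShape(float(delta))


@dataclass(frozen=True)
class TissueEdge:
    """Directed contact i -> j with surface midpoint eta (cell i frame)."""

    i: int
    j: int
    eta: float
    d: float
    alpha: float = 0.0

    @property
    def eta_rev(self) -> float:
        return wrap(self.eta + np.pi)


@dataclass
class TissueGraph:
    n_cells: int
    edges: List[TissueEdge]
    coords: Dict[int, Tuple[int, int]] = field(default_factory=dict)
    kind: str = "custom"

    def __post_init__(self):
        self.validate()

    def neighbors(self, i: int) -> List[TissueEdge]:
        return [e for e in self.edges if e.i == i]

    def edge(self, i: int, j: int) -> TissueEdge:
        for e in self.edges:
            if e.i == i and e.j == j:
                return e
        raise KeyError(f"no edge {i} -> {j}")

    def is_boundary(self, i: int) -> bool:
        return len(self.neighbors(i)) < 6 if self.kind != "chain" else len(self.neighbors(i)) < 2

    @property
    def widths(self) -> List[float]:
        return sorted({round(e.d, 12) for e in self.edges})

    def validate(self) -> None:
        index = {(e.i, e.j): e for e in self.edges}
        if len(index) != len(self.edges):
            raise ValueError("duplicate directed edges")
        for e in self.edges:
            if not (0 <= e.i < self.n_cells and 0 <= e.j < self.n_cells):
                raise ValueError("edge endpoint out of range")
            rev = index.get((e.j, e.i))
            if rev is None:
                raise ValueError(f"missing reverse edge for {e.i} -> {e.j}")
            if abs(wrap(rev.eta - e.eta - np.pi)) > 1e-9:
                raise ValueError(f"eta reciprocity violated on edge {e.i} -> {e.j}")
            if abs(rev.d - e.d) > 1e-12:
                raise ValueError(f"width symmetry violated on edge {e.i} -> {e.j}")
            if abs(rev.alpha - e.alpha) > 1e-12:
                raise ValueError(f"alpha symmetry violated on edge {e.i} -> {e.j}")
        counts = np.zeros(self.n_cells, dtype=int)
        for e in self.edges:
            counts[e.i] += 1
        if np.any(counts > 6):
            raise ValueError("a cell has more than 6 neighbours")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_cells": self.n_cells,
            "coords": {str(k): list(v) for k, v in sorted(self.coords.items())},
            "edges": [
                {"i": e.i, "j": e.j, "eta": e.eta, "d": e.d, "alpha": e.alpha}
                for e in self.edges
            ],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=False, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "TissueGraph":
        edges = [TissueEdge(e["i"], e["j"], e["eta"], e["d"], e.get("alpha", 0.0)) for e in d["edges"]]
        coords = {int(k): tuple(v) for k, v in d.get("coords", {}).items()}
        return cls(d["n_cells"], edges, coords, d.get("kind", "custom"))


def _pair(edges: List[TissueEdge], i: int, j: int, eta_ij: float, d: float) -> None:
    edges.append(TissueEdge(i, j, wrap(eta_ij), d))
    edges.append(TissueEdge(j, i, wrap(eta_ij + np.pi), d))


def chain(n: int, boundary: str = "open", shape: Optional[HexCellShape] = None) -> TissueGraph:
    """Straight row of cells: eta = 0 towards the next cell, pi back."""
    if n < 2:
        raise ValueError("chain needs at least 2 cells")
    if boundary not in ("open", "periodic"):
        raise ValueError("boundary must be 'open' or 'periodic'")
    shape = shape or hex_shape(np.pi / 3)
    edges: List[TissueEdge] = []
    for i in range(n - 1):
        _pair(edges, i, i + 1, 0.0, shape.delta)
    if boundary == "periodic":
        if n == 2:
            raise ValueError("periodic chain needs at least 3 cells")
        _pair(edges, n - 1, 0, 0.0, shape.delta)
    coords = {i: (0, i) for i in range(n)}
    return TissueGraph(n, edges, coords, kind="chain")


# odd-row offset lattice: row r is shifted right by half a cell when r is odd
_DIRECTIONS = ("E", "NE", "NW", "W", "SW", "SE")


def _neighbor_offset(direction: str, r: int) -> Tuple[int, int]:
    odd = r % 2
    return {
        "E": (0, 1),
        "W": (0, -1),
        "NE": (1, odd),
        "NW": (1, odd - 1),
        "SE": (-1, odd),
        "SW": (-1, odd - 1),
    }[direction]


def _direction_geometry(shape: HexCellShape) -> Dict[str, Tuple[float, float]]:
    d, dp = shape.delta, shape.delta_prime
    return {
        "E": (0.0, d),
        "NE": ((np.pi + d) / 4.0, dp),
        "NW": ((3.0 * np.pi - d) / 4.0, dp),
        "W": (np.pi, d),
        "SW": (-(3.0 * np.pi - d) / 4.0, dp),
        "SE": (-(np.pi + d) / 4.0, dp),
    }


def hex_sheet(
    rows: int,
    cols: int,
    boundary: str = "open",
    shape: Optional[HexCellShape] = None,
) -> TissueGraph:
    """Hexagonal sheet of ``rows x cols`` cells on an offset lattice."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be positive")
    if boundary not in ("open", "periodic"):
        raise ValueError("boundary must be 'open' or 'periodic'")
    if boundary == "periodic":
        if rows % 2 != 0:
            raise ValueError("periodic sheets need an even number of rows")
        # smaller tori make distinct contact surfaces wrap onto one neighbour
        if rows < 4 or cols < 3:
            raise ValueError("periodic sheets need at least 4 rows and 3 cols")
    shape = shape or hex_shape(np.pi / 3)
    geom = _direction_geometry(shape)
    index = {(r, c): r * cols + c for r in range(rows) for c in range(cols)}
    edges: List[TissueEdge] = []
    for (r, c), i in index.items():
        for direction in _DIRECTIONS:
            dr, dc = _neighbor_offset(direction, r)
            rr, cc = r + dr, c + dc
            if boundary == "periodic":
                rr %= rows
                cc %= cols
            elif not (0 <= rr < rows and 0 <= cc < cols):
                continue
            j = index[(rr, cc)]
            eta, width = geom[direction]
            edges.append(TissueEdge(i, j, wrap(eta), width))
    coords = {i: rc for rc, i in index.items()}
    return TissueGraph(rows * cols, edges, coords, kind="hex_sheet")


def winding(path: Sequence[str], shape: Optional[HexCellShape] = None) -> TissueGraph:
    """Single-file winding alignment following lattice steps.

    ``path`` is a sequence of direction names from
    ``{"E","NE","NW","W","SW","SE"}``; cell k+1 is placed in that direction
    from cell k and only consecutive cells are in contact.
    """
    shape = shape or hex_shape(np.pi / 3)
    geom = _direction_geometry(shape)
    edges: List[TissueEdge] = []
    coords = {0: (0, 0)}
    r, c = 0, 0
    for k, step in enumerate(path):
        if step not in geom:
            raise ValueError(f"unknown direction {step!r}")
        eta, width = geom[step]
        _pair(edges, k, k + 1, eta, width)
        dr, dc = _neighbor_offset(step, r)
        r, c = r + dr, c + dc
        if (r, c) in coords.values():
            raise ValueError("winding path revisits a cell")
        coords[k + 1] = (r, c)
    return TissueGraph(len(path) + 1, edges, coords, kind="winding")


def apply_heterogeneity(
    tissue: TissueGraph,
    alpha: float,
    eta_values: Sequence[float],
    tol: float = 1e-6,
) -> TissueGraph:
    """Return a copy with ``alpha`` set on edges whose eta matches a target.

    An edge and its reverse are modified together, keeping alpha symmetric.
    """
    targets = [wrap(v) for v in eta_values]

    def matches(eta: float) -> bool:
        return any(abs(wrap(eta - t)) < tol for t in targets)

    selected = {(e.i, e.j) for e in tissue.edges if matches(e.eta) or matches(e.eta_rev)}
    if not selected:
        raise ValueError("heterogeneity selector matched no edges")
    new_edges = [
        replace(e, alpha=alpha) if (e.i, e.j) in selected else e for e in tissue.edges
    ]
    return TissueGraph(tissue.n_cells, new_edges, dict(tissue.coords), tissue.kind)


def build_tissue(spec: dict) -> TissueGraph:
    """Build a tissue graph from a specification mapping.

    Keys: ``kind`` in {"chain", "hex_sheet", "winding"}; chain: ``n``,
    ``boundary``; hex_sheet: ``rows``, ``cols``, ``boundary``; winding:
    ``path``.  Optional ``delta`` (radians, default pi/3) and
    ``heterogeneity``: {"alpha": x, "eta": [values], "tol": t}.
    """
    spec = dict(spec)
    kind = spec.get("kind")
    shape = hex_shape(spec.get("delta", np.pi / 3))
    if kind == "chain":
        tissue = chain(spec["n"], spec.get("boundary", "open"), shape)
    elif kind == "hex_sheet":
        tissue = hex_sheet(spec["rows"], spec["cols"], spec.get("boundary", "open"), shape)
    elif kind == "winding":
        tissue = winding(spec["path"], shape)
    else:
        raise ValueError(f"unknown tissue kind {kind!r}")
    het = spec.get("heterogeneity")
    if het:
        tissue = apply_heterogeneity(tissue, het["alpha"], het["eta"], het.get("tol", 1e-6))
    return tissue
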