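"""Elastic spring network of the otolithic membrane over a bundle grid.

Bundles sit on a rectangular lattice with spacing ``d`` and are connected
by springs to their nearest and next-nearest (diagonal) neighbours.  The
spring stiffness is ``K`` in healthy tissue and ``K_d`` on every edge
touching a designated damage region.  Bundle motion is one-dimensional
along the row axis of the grid, so diagonal and transverse springs
contribute geometrically nonlinear restoring forces.

Offset convention (the single most error-prone piece of bookkeeping in
this model): for an edge (a, b),

    k = row(a) − row(b),   l = col(a) − col(b),

and the pair force is evaluated with ΔX = X_a − X_b.  The bundle motion
axis is along the row (k) direction, which is why ``k·d`` adds to ΔX in
the force law while ``l·d`` only enters the spring length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "GridSpec",
    "DamageRegion",
    "CouplingGraph",
    "build_coupling_graph",
    "pair_coupling_force",
    "total_coupling_forces",
]

# Valid neighbour offsets as (|k|, |l|)
_NEIGHBOR_OFFSETS = {(1, 0), (0, 1), (1, 1)}


@dataclass(frozen=True)
class GridSpec:
    """Geometry and stiffness of the coupled-bundle lattice.

    Defaults describe the healthy preparation: a 15×15 grid with 50 µm
    spacing and membrane stiffness K = 1.4 mN/m on every spring.
    """

    n_rows: int = 15
    n_cols: int = 15
    d: float = 50e-6
    K: float = 0.0014
    K_d: float = 0.0014

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError("grid must have n_rows, n_cols >= 1")
        if self.d <= 0:
            raise ConfigurationError("bundle spacing d must be > 0")
        if not 0.0 <= self.K_d <= self.K:
            raise ConfigurationError(
                f"damaged stiffness K_d={self.K_d!r} must satisfy 0 <= K_d <= K={self.K!r}"
            )

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def flat_index(self, row: int, col: int) -> int:
        return row * self.n_cols + col


@dataclass(frozen=True)
class DamageRegion:
    """Inclusive index block of bundles under a damaged patch of membrane.

    The default mirrors the damage layout used throughout: a 4×4 block in
    the low-index grid corner.  ``DamageRegion.none()`` gives an empty
    region (healthy tissue everywhere).

    ``rule`` decides which springs get the damaged stiffness:
    ``"touching"`` (default) damages every edge with at least one
    endpoint in the region — a degraded patch weakens every spring it
    anchors; ``"inside"`` only edges with both endpoints inside.
    """

    row_start: int = 0
    row_stop: int = 3
    col_start: int = 0
    col_stop: int = 3
    empty: bool = False
    rule: str = "touching"

    def __post_init__(self) -> None:
        if self.rule not in ("touching", "inside"):
            raise ConfigurationError(f"unknown damage rule {self.rule!r}")

    @classmethod
    def none(cls) -> "DamageRegion":
        return cls(empty=True)

    def contains(self, row, col):
        """Vectorized membership test for grid indices."""
        if self.empty:
            return np.zeros(np.broadcast(row, col).shape, dtype=bool)
        return (
            (np.asarray(row) >= self.row_start)
            & (np.asarray(row) <= self.row_stop)
            & (np.asarray(col) >= self.col_start)
            & (np.asarray(col) <= self.col_stop)
        )

    def validate_within(self, grid: GridSpec) -> None:
        if self.empty:
            return
        ok = (
            0 <= self.row_start <= self.row_stop < grid.n_rows
            and 0 <= self.col_start <= self.col_stop < grid.n_cols
        )
        if not ok:
            raise ConfigurationError(
                f"damage region rows [{self.row_start}, {self.row_stop}] × "
                f"cols [{self.col_start}, {self.col_stop}] does not fit a "
                f"{grid.n_rows}×{grid.n_cols} grid"
            )

    def focal_cell(self) -> tuple[int, int]:
        """A representative bundle inside the region (its centre cell)."""
        if self.empty:
            raise ConfigurationError("empty damage region has no focal cell")
        return (self.row_start + self.row_stop) // 2, (self.col_start + self.col_stop) // 2


@dataclass(frozen=True)
class CouplingGraph:
    """Undirected spring edge list with geometric offsets and stiffness.

    Arrays are index-aligned: edge ``e`` joins flat cells ``cell_a[e]`` and
    ``cell_b[e]`` with row/column offsets ``k[e]``, ``l[e]`` (first minus
    second) and stiffness ``stiffness[e]``.
    """

    n_rows: int
    n_cols: int
    d: float
    cell_a: np.ndarray = field(repr=False)
    cell_b: np.ndarray = field(repr=False)
    k: np.ndarray = field(repr=False)
    l: np.ndarray = field(repr=False)
    stiffness: np.ndarray = field(repr=False)

    @property
    def n_edges(self) -> int:
        return len(self.cell_a)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def to_table(self):
        """Edge list as a pandas DataFrame for inspection/export."""
        import pandas as pd

        return pd.DataFrame(
            {
                "cell_a_row": self.cell_a // self.n_cols,
                "cell_a_col": self.cell_a % self.n_cols,
                "cell_b_row": self.cell_b // self.n_cols,
                "cell_b_col": self.cell_b % self.n_cols,
                "k": self.k,
                "l": self.l,
                "stiffness": self.stiffness,
            }
        )


def build_coupling_graph(
    grid: GridSpec,
    damage: DamageRegion | None = None,
    damage_rule: str | None = None,
) -> CouplingGraph:
    """Enumerate nearest and next-nearest neighbour springs with stiffness.

    Edges are ordered row-major by the first endpoint, then by offset
    (E, SW, S, SE), so the graph is bit-reproducible.  An edge gets the
    damaged stiffness ``K_d`` when it touches the damage region: with the
    default rule ``"touching"`` one endpoint inside suffices (damaged
    tissue degrades every spring it anchors); with ``"inside"`` both
    endpoints must lie inside.

    Raises
    ------
    ConfigurationError
        If the damage region does not fit the grid or the rule is unknown.
    """
    if damage is None:
        damage = DamageRegion.none()
    damage.validate_within(grid)
    if damage_rule is None:
        damage_rule = damage.rule
    if damage_rule not in ("touching", "inside"):
        raise ConfigurationError(f"unknown damage_rule {damage_rule!r}")

    R, C = grid.n_rows, grid.n_cols
    # Offsets from the first endpoint to the second, in deterministic order.
    steps = [(0, 1), (1, -1), (1, 0), (1, 1)]
    a_rows, a_cols, b_rows, b_cols = [], [], [], []
    for i in range(R):
        for j in range(C):
            for di, dj in steps:
                bi, bj = i + di, j + dj
                if 0 <= bi < R and 0 <= bj < C:
                    a_rows.append(i)
                    a_cols.append(j)
                    b_rows.append(bi)
                    b_cols.append(bj)
    a_rows = np.asarray(a_rows, dtype=np.int64)
    a_cols = np.asarray(a_cols, dtype=np.int64)
    b_rows = np.asarray(b_rows, dtype=np.int64)
    b_cols = np.asarray(b_cols, dtype=np.int64)

    in_a = damage.contains(a_rows, a_cols)
    in_b = damage.contains(b_rows, b_cols)
    damaged = (in_a | in_b) if damage_rule == "touching" else (in_a & in_b)
    stiffness = np.where(damaged, grid.K_d, grid.K).astype(float)

    return CouplingGraph(
        n_rows=R,
        n_cols=C,
        d=grid.d,
        cell_a=a_rows * C + a_cols,
        cell_b=b_rows * C + b_cols,
        k=a_rows - b_rows,
        l=a_cols - b_cols,
        stiffness=stiffness,
    )


def pair_coupling_force(delta_X, k, l, K_v, d):
    """Axial spring force K_v·(1 − L0/L)·(ΔX + k·d) for one edge.

    ``L = sqrt((ΔX + k·d)² + (l·d)²)`` is the current spring length and
    ``L0 = sqrt(k² + l²)·d`` its rest length (the undisplaced separation),
    so the force vanishes identically at ΔX = 0.  Antisymmetric under the
    simultaneous swap (ΔX, k, l) → (−ΔX, −k, −l).

    Scalar or array inputs; offsets must satisfy (|k|, |l|) ∈
    {(1,0), (0,1), (1,1)}.
    """
    k = np.atleast_1d(np.asarray(k))
    l = np.atleast_1d(np.asarray(l))
    kk, ll = np.broadcast_arrays(np.abs(k), np.abs(l))
    offs = set(zip(kk.ravel().tolist(), ll.ravel().tolist()))
    if not offs <= _NEIGHBOR_OFFSETS:
        raise InvalidInputError(f"invalid neighbour offsets {sorted(offs - _NEIGHBOR_OFFSETS)}")
    if np.any(np.asarray(d) <= 0):
        raise InvalidInputError("spacing d must be > 0")
    out = _pair_force_raw(np.asarray(delta_X, dtype=float), k, l, K_v, d)
    if out.shape == (1,) and np.isscalar(delta_X):
        return out[0]
    return out


def _pair_force_raw(delta_X, k, l, K_v, d):
    axial = delta_X + k * d
    length = np.sqrt(axial**2 + (l * d) ** 2)
    if np.any(length == 0):
        raise InvalidInputError("degenerate spring geometry: zero length")
    L0 = np.sqrt((k**2 + l**2).astype(float)) * d
    return K_v * (1.0 - L0 / length) * axial


def total_coupling_forces(positions: np.ndarray, graph: CouplingGraph) -> np.ndarray:
    """Net membrane force on every bundle (flat array, N).

    Each edge is evaluated once with ΔX = X_first − X_second and applied
    with opposite signs to its endpoints, so internal forces cancel
    pairwise and the total momentum imparted by the membrane is zero.
    """
    positions = np.asarray(positions, dtype=float).ravel()
    if positions.shape[0] != graph.n_cells:
        raise InvalidInputError(
            f"positions has {positions.shape[0]} entries for a {graph.n_cells}-cell graph"
        )
    if np.any(~np.isfinite(positions)):
        raise InvalidInputError("non-finite positions")
    # Offsets were validated when the graph was built; skip per-call checks.
    g = _pair_force_raw(
        positions[graph.cell_a] - positions[graph.cell_b],
        graph.k,
        graph.l,
        graph.stiffness,
        graph.d,
    )
    forces = np.zeros(graph.n_cells)
    # Force on the second endpoint is +g (a bundle is pulled along +x when
    # its neighbour in the +k direction is displaced further); on the
    # first it is −g by Newton's third law.
    np.add.at(forces, graph.cell_b, g)
    np.add.at(forces, graph.cell_a, -g)
    return forces


def pair_elastic_energy(positions: np.ndarray, graph: CouplingGraph) -> float:
    """Total spring energy Σ K_v/2·(L − L0)²; forces are −∂E/∂X."""
    positions = np.asarray(positions, dtype=float).ravel()
    dX = positions[graph.cell_a] - positions[graph.cell_b]
    axial = dX + graph.k * graph.d
    length = np.sqrt(axial**2 + (graph.l * graph.d) ** 2)
    L0 = np.sqrt((graph.k**2 + graph.l**2).astype(float)) * graph.d
    return float(np.sum(0.5 * graph.stiffness * (length - L0) ** 2))
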