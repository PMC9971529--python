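"""Time integration of the coupled stochastic bundle grid.

The drift (deterministic part of the equations of motion) is advanced
with classical fourth-order Runge–Kutta; each step's white-noise draws
are treated as constant external forces across the four stages
(stage-frozen), which is exact RK4 for the drift and Euler–Maruyama
consistent for the diffusion.  A plain Euler–Maruyama scheme is available
as a cross-check.

Two execution paths produce the same trajectories: a vectorized numpy
reference built directly on :func:`otogrid.model_core.drift`, and a
numba-compiled fast path (:mod:`otogrid._kernel`) used by default for
production runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from . import _kernel
from .errors import ConfigurationError, IntegrationError
from .grid_coupling import CouplingGraph, DamageRegion, GridSpec, build_coupling_graph, total_coupling_forces
from .model_core import (
    DEFAULT_MOTOR_MODE,
    MOTOR_MODES,
    BundleState,
    CellParams,
    ParameterSet,
    drift,
    open_probability,
)
from .stochastics import HeterogeneitySpec, NoiseChannels, sample_heterogeneity, split_streams

__all__ = ["RunConfig", "Trace", "GridState", "step", "simulate"]

# The state of the whole grid is a BundleState whose fields are flat
# per-cell arrays.
GridState = BundleState

# Abort thresholds: physical trajectories stay within tens of nm and
# C within [C0, C_M]; excursions beyond these signal a unit mistake.
X_GUARD = 1e-6  # m
C_GUARD_FACTOR = 10.0  # × C_M


@dataclass(frozen=True)
class RunConfig:
    """Integration and recording settings for one simulation.

    Defaults give the standard protocol: 500,000 steps of 20 µs (10 s of
    simulated time) after a 50,000-step (1 s) burn-in that is discarded
    so stationary statistics do not depend on the arbitrary initial
    condition.
    """

    dt: float = 20e-6
    n_steps: int = 500_000
    burn_in_steps: int = 50_000
    record_stride: int = 1
    recorded_cells: str | Sequence[tuple[int, int]] = "all"
    seed: int = 0
    scheme: str = "rk4"
    motor_mode: str = DEFAULT_MOTOR_MODE
    noise: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.n_steps < 1:
            raise ConfigurationError("n_steps must be >= 1")
        if self.burn_in_steps < 0:
            raise ConfigurationError("burn_in_steps must be >= 0")
        if self.record_stride < 1:
            raise ConfigurationError("record_stride must be >= 1")
        if self.scheme not in ("rk4", "euler"):
            raise ConfigurationError(f"unknown scheme {self.scheme!r}")
        if self.motor_mode not in MOTOR_MODES:
            raise ConfigurationError(f"unknown motor_mode {self.motor_mode!r}")


@dataclass
class Trace:
    """Recorded trajectories of selected bundles plus full run metadata.

    ``times`` starts at 0 (the end of burn-in) and ends at
    ``n_steps·dt``; arrays are (n_times, n_recorded_cells).  ``P_o`` is
    computed from the recorded X, X_a via the two-state channel model.
    """

    times: np.ndarray
    X: np.ndarray
    X_a: np.ndarray
    C: np.ndarray
    P_o: np.ndarray
    cells: list[tuple[int, int]]
    metadata: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def cell_index(self, row: int, col: int) -> int:
        """Column index of a recorded cell."""
        try:
            return self.cells.index((row, col))
        except ValueError:
            raise KeyError(f"cell ({row}, {col}) was not recorded") from None

    def column(self, name: str, row: int, col: int) -> np.ndarray:
        i = self.cell_index(row, col)
        return getattr(self, name)[:, i]

    # -- serialization -------------------------------------------------
    def to_hdf5(self, path) -> None:
        """Write /meta (JSON attrs), /time and /cells/<r>_<c>/{X,Xa,C,Po}."""
        import json

        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["metadata"] = json.dumps(self.metadata)
            f.create_dataset("time", data=self.times)
            grp = f.create_group("cells")
            for i, (r, c) in enumerate(self.cells):
                g = grp.create_group(f"{r}_{c}")
                g.create_dataset("X", data=self.X[:, i])
                g.create_dataset("Xa", data=self.X_a[:, i])
                g.create_dataset("C", data=self.C[:, i])
                g.create_dataset("Po", data=self.P_o[:, i])

    @classmethod
    def from_hdf5(cls, path) -> "Trace":
        import json

        import h5py

        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["metadata"])
            times = f["time"][:]
            cells, cols = [], []
            for name in f["cells"]:
                r, c = (int(v) for v in name.split("_"))
                cells.append((r, c))
            cells.sort()
            X = np.column_stack([f[f"cells/{r}_{c}/X"][:] for r, c in cells])
            Xa = np.column_stack([f[f"cells/{r}_{c}/Xa"][:] for r, c in cells])
            C = np.column_stack([f[f"cells/{r}_{c}/C"][:] for r, c in cells])
            Po = np.column_stack([f[f"cells/{r}_{c}/Po"][:] for r, c in cells])
        return cls(times=times, X=X, X_a=Xa, C=C, P_o=Po, cells=cells, metadata=meta)

    def to_frame(self):
        """Long-format DataFrame (time, cell_row, cell_col, X, Xa, C, Po)."""
        import pandas as pd

        frames = []
        for i, (r, c) in enumerate(self.cells):
            frames.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "cell_row": r,
                        "cell_col": c,
                        "X": self.X[:, i],
                        "Xa": self.X_a[:, i],
                        "C": self.C[:, i],
                        "Po": self.P_o[:, i],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def step(
    state: GridState,
    graph: CouplingGraph,
    cells: CellParams,
    params: ParameterSet,
    noise: NoiseChannels,
    dt: float,
    scheme: str = "rk4",
    motor_mode: str = DEFAULT_MOTOR_MODE,
) -> GridState:
    """One integration step of the whole grid (numpy reference path).

    The coupling force is recomputed from the stage positions at every
    RK4 stage; the step's noise draws are held fixed across stages and
    enter inside the bracketed force/concentration terms of the
    equations of motion.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    y = (np.asarray(state.X, float).copy(), np.asarray(state.X_a, float).copy(),
         np.asarray(state.C, float).copy())

    def rhs(X, Xa, C):
        F = total_coupling_forces(X, graph)
        return drift(
            BundleState(X, Xa, C), F, cells, params,
            eta=noise.eta, eta_a=noise.eta_a, delta_c=noise.delta_c,
            motor_mode=motor_mode,
        )

    k1 = rhs(*y)
    if scheme == "euler":
        out = tuple(y[i] + dt * k1[i] for i in range(3))
    elif scheme == "rk4":
        k2 = rhs(*(y[i] + 0.5 * dt * k1[i] for i in range(3)))
        k3 = rhs(*(y[i] + 0.5 * dt * k2[i] for i in range(3)))
        k4 = rhs(*(y[i] + dt * k3[i] for i in range(3)))
        out = tuple(
            y[i] + (dt / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            for i in range(3)
        )
    else:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    new = GridState(X=out[0], X_a=out[1], C=out[2])
    bad = ~(np.isfinite(out[0]) & np.isfinite(out[1]) & np.isfinite(out[2]))
    if np.any(bad):
        cell = int(np.flatnonzero(bad)[0])
        raise IntegrationError(f"non-finite state at cell {cell}", cell=cell)
    return new


def _resolve_recorded(run: RunConfig, grid: GridSpec) -> tuple[list[tuple[int, int]], np.ndarray]:
    if isinstance(run.recorded_cells, str):
        if run.recorded_cells != "all":
            raise ConfigurationError(f"unknown recorded_cells spec {run.recorded_cells!r}")
        cells = [(r, c) for r in range(grid.n_rows) for c in range(grid.n_cols)]
    else:
        cells = [tuple(rc) for rc in run.recorded_cells]
        for r, c in cells:
            if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
                raise ConfigurationError(f"recorded cell ({r}, {c}) outside grid")
    idx = np.asarray([r * grid.n_cols + c for r, c in cells], dtype=np.int64)
    return cells, idx


def simulate(
    run: RunConfig,
    grid: GridSpec,
    damage: DamageRegion | None = None,
    het: HeterogeneitySpec | None = None,
    params: ParameterSet | None = None,
    cells_override: CellParams | None = None,
    engine: str = "numba",
    chunk_steps: int = 20_000,
    init: str = "midgating",
) -> Trace:
    """Run burn-in plus ``n_steps`` of the coupled grid and record a Trace.

    Heterogeneity is drawn from ``het.seed`` and the dynamical noise from
    ``run.seed`` on independent streams, so sweeps can hold the quenched
    disorder fixed while varying noise realizations.  The trace's first
    row is the state at the end of burn-in (t = 0); rows follow every
    ``record_stride`` steps, so the recorded span is exactly
    ``n_steps·dt``.

    ``cells_override`` bypasses heterogeneity sampling (used for motor-
    disabled passive baselines and single-cell experiments).
    """
    if params is None:
        params = ParameterSet()
    if het is None:
        het = HeterogeneitySpec()
    if damage is None:
        damage = DamageRegion.none()
    graph = build_coupling_graph(grid, damage)
    if cells_override is not None:
        cell_params = cells_override
    else:
        cell_params = sample_heterogeneity(het, grid, params)
    _, noise_rng = split_streams(run.seed)

    rec_cells, rec_idx = _resolve_recorded(run, grid)
    n = grid.n_cells
    n_rows_out = run.n_steps // run.record_stride + 1
    recX = np.empty((n_rows_out, len(rec_cells)))
    recXa = np.empty_like(recX)
    recC = np.empty_like(recX)

    # Initial condition.  "midgating" places every bundle at the
    # half-open channel state (X = 0, X_a = −δ·ln A, C at its P_o = 1/2
    # stationary value), i.e. on the operating branch of the adaptation
    # cycle; "rest" is the naive origin.  Burn-in erases the difference
    # for stationary statistics, but midgating avoids the huge startup
    # transient of the closed-channel state.
    if init == "midgating":
        X = np.zeros(n)
        Xa = np.full(n, -params.delta * np.log(params.A))
        C = np.full(n, params.C0 + 0.5 * (params.C_M - params.C0))
    elif init == "rest":
        X = np.zeros(n)
        Xa = np.zeros(n)
        C = np.full(n, float(params.C0))
    else:
        raise ConfigurationError(f"unknown init {init!r}")
    if run.burn_in_steps == 0:
        recX[0] = X[rec_idx]
        recXa[0] = Xa[rec_idx]
        recC[0] = C[rec_idx]

    a0 = np.broadcast_to(np.asarray(cell_params.a0, float), (n,)).copy()
    fmax = np.broadcast_to(np.asarray(cell_params.f_max, float), (n,)).copy()
    p1 = np.broadcast_to(np.asarray(cell_params.p1, float), (n,)).copy()

    if run.noise:
        sd_eta = np.sqrt(2.0 * params.k_b * params.T * params.lambda_hb / run.dt)
        sd_eta_a = np.sqrt(2.0 * params.k_b * params.T_a * params.lambda_a / run.dt)
        dc_var_coef = 2.0 * params.C_M**2 * params.tau_c / (params.N * run.dt)
    else:
        sd_eta = sd_eta_a = dc_var_coef = 0.0

    total_steps = run.burn_in_steps + run.n_steps
    if engine == "numba":
        ekd = graph.k.astype(float) * graph.d
        eld2 = (graph.l.astype(float) * graph.d) ** 2
        eL0 = np.sqrt((graph.k**2 + graph.l**2).astype(float)) * graph.d
        step0 = 0
        while step0 < total_steps:
            m = min(chunk_steps, total_steps - step0)
            if run.noise:
                normals = noise_rng.standard_normal((m, 3, n))
            else:
                normals = np.zeros((m, 3, n))
            status, where, cell = _kernel._advance(
                X, Xa, C, normals, run.dt, step0, run.burn_in_steps,
                run.record_stride, rec_idx, recX, recXa, recC,
                a0, fmax, p1,
                params.lambda_hb, params.lambda_a, params.K_gs, params.K_sp,
                params.K_es, params.X_es, params.D, np.log(params.A),
                params.delta, params.tau, params.C0, params.C_M, params.p0,
                params.gamma,
                sd_eta, sd_eta_a, dc_var_coef,
                graph.cell_a, graph.cell_b, ekd, eld2, eL0, graph.stiffness,
                run.scheme == "rk4", MOTOR_MODES.index(run.motor_mode),
                X_GUARD, C_GUARD_FACTOR * params.C_M,
            )
            if status == _kernel.BLOWUP:
                raise IntegrationError(
                    f"state out of bounds at step {where}, cell {cell} "
                    f"(|X| > {X_GUARD} m or |C| > {C_GUARD_FACTOR}·C_M)",
                    step=int(where), cell=int(cell),
                )
            step0 += m
    elif engine == "numpy":
        state = GridState(X=X, X_a=Xa, C=C)
        for s in range(total_steps):
            z = noise_rng.standard_normal((3, n)) if run.noise else np.zeros((3, n))
            Po = open_probability(state.X, state.X_a, params)
            noise = NoiseChannels(
                eta=z[0] * sd_eta,
                eta_a=z[1] * sd_eta_a,
                delta_c=z[2] * np.sqrt(dc_var_coef * Po * (1.0 - Po)),
            )
            try:
                state = step(state, graph, cell_params, params, noise, run.dt,
                             scheme=run.scheme, motor_mode=run.motor_mode)
            except IntegrationError as err:
                raise IntegrationError(str(err), step=s, cell=err.cell) from None
            done = s + 1 - run.burn_in_steps
            if done >= 0 and done % run.record_stride == 0:
                row = done // run.record_stride
                recX[row] = np.asarray(state.X)[rec_idx]
                recXa[row] = np.asarray(state.X_a)[rec_idx]
                recC[row] = np.asarray(state.C)[rec_idx]
    else:
        raise ConfigurationError(f"unknown engine {engine!r}")

    times = np.arange(n_rows_out) * (run.dt * run.record_stride)
    Po = open_probability(recX, recXa, params)
    meta = {
        "run": asdict(run) if not isinstance(run.recorded_cells, str) else
               {**asdict(run), "recorded_cells": run.recorded_cells},
        "grid": asdict(grid),
        "damage": asdict(damage),
        "heterogeneity": asdict(het),
        "params": asdict(params),
        "engine": engine,
        "code_version": _code_version(),
    }
    return Trace(times=times, X=recX, X_a=recXa, C=recC, P_o=Po,
                 cells=rec_cells, metadata=meta)


def _code_version() -> str:
    try:
        from importlib.metadata import version

        return version("otogrid")
    except Exception:  # pragma: no cover
        return "unknown"
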