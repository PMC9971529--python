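"""Single-bundle biophysics: parameters, state, and deterministic dynamics.

A vestibular hair bundle is modelled by three coupled degrees of freedom:
the bundle tip position ``X`` (m), the position of the myosin adaptation
motors ``X_a`` (m), and the calcium concentration ``C`` (M) at the motor
binding site.  Mechanotransduction (MET) channels are treated as two-state
elements whose quasi-static open probability ``P_o`` is a Boltzmann
function of gating-spring extension.  The myosin motors exert a
calcium-regulated stall force that closes an active feedback loop capable
of producing limit-cycle oscillations of the bundle.

All quantities are SI (m, s, N, M, J).  Every function in this module is
pure and broadcasts over numpy arrays, so the same code serves a single
bundle and a whole grid of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

from .errors import ConfigurationError, InvalidInputError

ArrayLike = Union[float, np.ndarray]

__all__ = [
    "ParameterSet",
    "CellParams",
    "BundleState",
    "open_probability",
    "motor_binding_probability",
    "single_motor_force",
    "drift",
]


@dataclass(frozen=True)
class ParameterSet:
    """Global physical constants of the hair-bundle model.

    Defaults are the published bullfrog-sacculus values.  The derived
    constants ``D`` (gating displacement), ``A`` (gating constant) and
    ``delta`` (gating length scale) are exposed as properties so they are
    recomputed from their constituents on every access and can never go
    stale after a ``dataclasses.replace``.

    Attributes
    ----------
    lambda_hb : float
        Friction coefficient of the hair bundle (N·s/m).
    lambda_a : float
        Friction coefficient of the adaptation motors (N·s/m).
    K_gs, K_sp, K_es : float
        Stiffness of the combined gating springs, the stereociliary
        pivots (plus load), and the extent spring (N/m).
    X_es : float
        Resting deflection of the extent spring (m).
    d_gs : float
        Gating-spring elongation on channel opening (m).
    gamma : float
        Geometrical gain of stereociliary shear motion (dimensionless).
    tau, tau_c : float
        Calcium-feedback time constant and MET-channel dwell time (s).
    C0, C_M : float
        Minimum and maximum calcium concentration at the motor (M).
    N, N_a : float
        Number of stereocilia and of myosin motors per bundle.
    k_b, T, T_a : float
        Boltzmann constant (J/K), bath temperature and effective motor
        temperature (K).  The default ``T_a`` is 1.5·T.
    DeltaG : float
        Intrinsic free-energy change on MET channel opening (J).
    p0 : float
        Resting myosin-binding probability (dimensionless).
    """

    lambda_hb: float = 2.8e-6
    lambda_a: float = 10e-6
    K_gs: float = 750e-6
    K_sp: float = 600e-6
    K_es: float = 140e-6
    X_es: float = 20e-9
    d_gs: float = 8.7e-9
    gamma: float = 0.14
    tau: float = 0.1e-3
    tau_c: float = 1e-3
    C0: float = 0.0
    C_M: float = 250e-3
    N: float = 50.0
    N_a: float = 3000.0
    k_b: float = 1.38e-23
    T: float = 300.0
    T_a: float = 450.0
    DeltaG: float = 4.14e-20
    p0: float = 0.2

    def __post_init__(self) -> None:
        positive = {
            "lambda_hb": self.lambda_hb,
            "lambda_a": self.lambda_a,
            "K_gs": self.K_gs,
            "K_sp": self.K_sp,
            "K_es": self.K_es,
            "d_gs": self.d_gs,
            "gamma": self.gamma,
            "tau": self.tau,
            "tau_c": self.tau_c,
            "N": self.N,
            "N_a": self.N_a,
            "k_b": self.k_b,
            "T": self.T,
            "T_a": self.T_a,
        }
        for name, value in positive.items():
            if not np.isfinite(value) or value <= 0:
                raise ConfigurationError(f"{name} must be finite and > 0, got {value!r}")
        if not 0.0 <= self.p0 <= 1.0:
            raise ConfigurationError(f"p0 must lie in [0, 1], got {self.p0!r}")
        if self.C0 > self.C_M:
            raise ConfigurationError(f"C0 ({self.C0!r}) must not exceed C_M ({self.C_M!r})")
        if self.A <= 1.0:
            raise ConfigurationError("gating constant A must exceed 1")

    @property
    def D(self) -> float:
        """Gating displacement d_gs/gamma (m)."""
        return self.d_gs / self.gamma

    @property
    def A(self) -> float:
        """Gating constant exp([ΔG + K_gs·D²/(2N)] / k_b·T)."""
        energy = self.DeltaG + self.K_gs * self.D**2 / (2.0 * self.N)
        return float(np.exp(energy / (self.k_b * self.T)))

    @property
    def delta(self) -> float:
        """Gating length scale N·k_b·T/(K_gs·D) (m)."""
        return self.N * self.k_b * self.T / (self.K_gs * self.D)

    def with_(self, **changes) -> "ParameterSet":
        """Return a copy with the given fields replaced (revalidated)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class CellParams:
    """Per-bundle heterogeneity: rate factor, motor force and Ca feedback.

    ``a0`` uniformly rescales all three equations of motion in time and
    therefore sets the bundle's characteristic frequency.  ``f_max`` is the
    maximal collective motor force; ``S`` the dimensionless calcium
    feedback strength, tied to the binding-probability slope ``p1`` by
    S = −C_M·p1/p0.  Fields may be scalars or equal-shaped numpy arrays
    (one entry per grid cell).
    """

    a0: ArrayLike = 1.0
    f_max: ArrayLike = 352e-12
    S: ArrayLike = 0.65
    p1: ArrayLike = field(default=None)  # type: ignore[assignment]
    # Reference constants used to keep S and p1 consistent.
    _p0: float = 0.2
    _C_M: float = 250e-3

    def __post_init__(self) -> None:
        if self.p1 is None:
            object.__setattr__(self, "p1", -np.asarray(self.S) * self._p0 / self._C_M)
        a0 = np.asarray(self.a0, dtype=float)
        if np.any(~np.isfinite(a0)) or np.any(a0 <= 0):
            raise ConfigurationError("a0 must be finite and > 0")
        if np.any(np.asarray(self.f_max) < 0):
            raise ConfigurationError("f_max must be non-negative")
        expected_p1 = -np.asarray(self.S) * self._p0 / self._C_M
        if not np.allclose(np.asarray(self.p1), expected_p1, rtol=1e-12, atol=1e-300):
            raise ConfigurationError("p1 inconsistent with S = -C_M*p1/p0")

    @classmethod
    def from_feedback(
        cls, a0: ArrayLike, f_max: ArrayLike, S: ArrayLike, params: ParameterSet
    ) -> "CellParams":
        """Build CellParams from feedback strength S using the given constants."""
        return cls(a0=a0, f_max=f_max, S=S, p1=None, _p0=params.p0, _C_M=params.C_M)


@dataclass
class BundleState:
    """Instantaneous state of one bundle (or arrays for a whole grid)."""

    X: ArrayLike = 0.0
    X_a: ArrayLike = 0.0
    C: ArrayLike = 0.0

    def validate(self) -> None:
        for name in ("X", "X_a", "C"):
            v = np.asarray(getattr(self, name))
            if np.any(~np.isfinite(v)):
                raise InvalidInputError(f"non-finite value in state component {name}")


def _stable_sigmoid(z: ArrayLike) -> np.ndarray:
    """1/(1+exp(-z)) without overflow for any finite z."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def open_probability(X: ArrayLike, X_a: ArrayLike, params: ParameterSet) -> np.ndarray:
    """MET-channel open probability for gating-spring extension X − X_a.

    Two-state Boltzmann form P_o = 1/(1 + A·exp(−(X − X_a)/δ)).  Written
    as a numerically stable logistic in z = (X − X_a)/δ − ln A, so it
    saturates smoothly to 0 or 1 for large |X − X_a| instead of
    overflowing.

    Raises
    ------
    InvalidInputError
        If any input is non-finite.
    """
    X = np.asarray(X, dtype=float)
    X_a = np.asarray(X_a, dtype=float)
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(X_a)):
        raise InvalidInputError("open_probability requires finite X and X_a")
    log_A = (params.DeltaG + params.K_gs * params.D**2 / (2.0 * params.N)) / (
        params.k_b * params.T
    )
    z = (X - X_a) / params.delta - log_A
    return _stable_sigmoid(z)


def motor_binding_probability(
    C: ArrayLike, cell: CellParams, params: ParameterSet, clamp: bool = True
) -> np.ndarray:
    """Probability that myosin motors are bound to actin, p(C) = p0 + p1·C.

    The affine form can leave [0, 1] when noise drives C to extreme
    values; since p is a probability it is clamped to the unit interval by
    default.  Pass ``clamp=False`` for exact-equation comparisons.
    """
    C = np.asarray(C, dtype=float)
    if np.any(~np.isfinite(C)):
        raise InvalidInputError("motor_binding_probability requires finite C")
    p = params.p0 + np.asarray(cell.p1) * C
    if clamp:
        p = np.clip(p, 0.0, 1.0)
    return p


# How the per-motor force f is obtained from the bundle's maximal motor
# force f_max.  The motor stall force is γ·N_a·f·p(C) in every mode:
#
# * "ensemble" (default): f = f_max/(γ·N_a) — f_max is the maximal stall
#   force of the whole motor ensemble (stall = f_max·p(C)).  Calibration
#   of the single-bundle dynamics shows this is the only constant-force
#   reading under which bundles across most of the sampled f_max range
#   [87, 352] pN can be poised in the oscillatory/excitable regime.
# * "p0": f = f_max/(N_a·p0) — divide by the resting binding
#   probability (stall = γ·f_max·p(C)/p0).
# * "dynamic": f = f_max/(N_a·P_o) with the instantaneous channel-open
#   probability — the stall force diverges as P_o → 0, so this mode is
#   for sensitivity checks only (use a mid-gating initial state).
MOTOR_MODES = ("ensemble", "p0", "dynamic")
DEFAULT_MOTOR_MODE = "ensemble"


def single_motor_force(
    cell: CellParams, params: ParameterSet, mode: str = DEFAULT_MOTOR_MODE
) -> np.ndarray:
    """Constant per-motor force f (N) under the given motor-force mode.

    See :data:`MOTOR_MODES`; the "dynamic" mode has no constant f and is
    rejected here (it is resolved state-dependently inside ``drift``).
    """
    f_max = np.asarray(cell.f_max)
    if mode == "ensemble":
        return f_max / (params.gamma * params.N_a)
    if mode == "p0":
        return f_max / (params.N_a * params.p0)
    raise ConfigurationError(f"no constant single-motor force in mode {mode!r}")


def drift(
    state: BundleState,
    F_coupling: ArrayLike,
    cell: CellParams,
    params: ParameterSet,
    eta: ArrayLike = 0.0,
    eta_a: ArrayLike = 0.0,
    delta_c: ArrayLike = 0.0,
    clamp_p: bool = True,
    motor_mode: str = DEFAULT_MOTOR_MODE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time derivatives (dX/dt, dX_a/dt, dC/dt) of the bundle equations.

    The three equations of motion, solved for the derivatives::

        dX/dt  = (a0/λ)  · [ −K_gs·(X − X_a − D·P_o) − K_sp·X + F_K + η ]
        dXa/dt = (a0/λ_a)· [  K_gs·(X − X_a − D·P_o) − γ·N_a·f·p(C)
                              + K_es·(X_a + X_es) + η_a ]
        dC/dt  = (a0/τ)  · [  C0 − C + C_M·P_o + δc ]

    The noise terms default to zero so the same function is the
    deterministic drift; the integrator passes the step's frozen noise
    draws so they enter inside the brackets exactly as written.

    Returns (m/s, m/s, M/s), broadcast over cells.
    """
    state.validate()
    X = np.asarray(state.X, dtype=float)
    X_a = np.asarray(state.X_a, dtype=float)
    C = np.asarray(state.C, dtype=float)
    F_coupling = np.asarray(F_coupling, dtype=float)
    if np.any(~np.isfinite(F_coupling)):
        raise InvalidInputError("non-finite coupling force")

    Po = open_probability(X, X_a, params)
    F_gs = params.K_gs * (X - X_a - params.D * Po)
    p = motor_binding_probability(C, cell, params, clamp=clamp_p)
    if motor_mode == "dynamic":
        f = np.asarray(cell.f_max) / (params.N_a * np.maximum(Po, 1e-12))
    elif motor_mode in ("ensemble", "p0"):
        f = single_motor_force(cell, params, mode=motor_mode)
    else:
        raise ConfigurationError(f"unknown motor_mode {motor_mode!r}")

    a0 = np.asarray(cell.a0, dtype=float)
    dX = (a0 / params.lambda_hb) * (-F_gs - params.K_sp * X + F_coupling + eta)
    dXa = (a0 / params.lambda_a) * (
        F_gs
        - params.gamma * params.N_a * f * p
        + params.K_es * (X_a + params.X_es)
        + eta_a
    )
    dC = (a0 / params.tau) * (params.C0 - C + params.C_M * Po + delta_c)
    return dX, dXa, dC
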