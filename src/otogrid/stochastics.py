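"""Quenched heterogeneity and dynamical noise for the bundle grid.

Two independent sources of randomness enter the model and are kept on
separate, independently seeded streams:

* **Quenched heterogeneity** — each bundle is assigned its own rate
  factor ``a0`` (normal, mean 1.5, SD 0.25, truncated positive), maximal
  motor force ``f_max`` (uniform on [87, 352] pN) and calcium feedback
  strength ``S`` tied linearly to ``f_max``.  These stay fixed for a
  whole run and give the grid its dispersion of characteristic
  frequencies.
* **Dynamical noise** — three white Gaussian channels per bundle per
  timestep: a thermal force on the bundle, a (hotter) effective thermal
  force on the motors, and a binomial-channel calcium fluctuation whose
  variance tracks P_o(1 − P_o).

Because a Dirac-delta correlated force of intensity 2·k_b·T·λ is held
constant over a step of length dt, its discrete stand-in is a Gaussian of
variance 2·k_b·T·λ/dt (not ·dt — the classic √dt error), so that the
variance of the accumulated impulse over the step is correct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .grid_coupling import GridSpec
from .model_core import CellParams, ParameterSet

__all__ = [
    "HeterogeneitySpec",
    "NoiseChannels",
    "sample_heterogeneity",
    "noise_std",
    "generate_noise",
    "split_streams",
]

# Floor applied when truncating the a0 distribution.  Mean 1.5 with
# SD 0.25 puts zero six sigma below the mean, so the floor is a guard
# against unphysical non-positive rate factors, not a real censoring.
A0_FLOOR = 0.05


@dataclass(frozen=True)
class HeterogeneitySpec:
    """Distribution parameters for the per-cell quenched disorder.

    ``S_at_fmax_low``/``S_at_fmax_high`` are the endpoints of the line in
    (f_max, S) space along which bundles are placed; the defaults were
    fixed once by the calibration scan (CLI ``otogrid calibrate-line``)
    so that uncoupled bundles are motile while the healthy coupled grid
    stays quiescent (see docs/methods.md).
    """

    a0_mean: float = 1.5
    a0_sd: float = 0.25
    fmax_low: float = 87e-12
    fmax_high: float = 352e-12
    S_at_fmax_low: float = 0.1
    S_at_fmax_high: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a0_sd < 0:
            raise ConfigurationError("a0_sd must be >= 0")
        if not self.fmax_low < self.fmax_high:
            raise ConfigurationError("fmax_low must be < fmax_high")
        if self.a0_mean <= 0:
            raise ConfigurationError("a0_mean must be > 0")


@dataclass
class NoiseChannels:
    """One step's frozen noise draws, one entry per cell.

    eta: force on the bundle (N); eta_a: force on the motors (N);
    delta_c: calcium fluctuation (M).
    """

    eta: np.ndarray
    eta_a: np.ndarray
    delta_c: np.ndarray


def split_streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Independent (heterogeneity, dynamical-noise) generators from one seed.

    Spawning from a single SeedSequence guarantees the two streams never
    overlap, so redrawing the dynamical noise can never perturb the cell
    parameters and vice versa.
    """
    het_ss, noise_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(het_ss), np.random.default_rng(noise_ss)


def sample_heterogeneity(
    spec: HeterogeneitySpec,
    grid: GridSpec,
    params: ParameterSet | None = None,
    rng: np.random.Generator | None = None,
) -> CellParams:
    """Draw per-cell (a0, f_max, S) arrays for every bundle on the grid.

    a0 ~ Normal(mean, sd) truncated at a small positive floor;
    f_max ~ Uniform(low, high), drawn independently of a0; S follows by
    linear interpolation in f_max between the spec's two endpoints, and
    p1 = −S·p0/C_M.  Fully reproducible from ``spec.seed`` (or an
    explicit generator).

    Returns a :class:`~otogrid.model_core.CellParams` whose fields are
    flat arrays of length ``grid.n_cells`` (row-major).
    """
    if params is None:
        params = ParameterSet()
    if rng is None:
        rng, _ = split_streams(spec.seed)
    n = grid.n_cells
    a0 = rng.normal(spec.a0_mean, spec.a0_sd, size=n)
    a0 = np.maximum(a0, A0_FLOOR)
    f_max = rng.uniform(spec.fmax_low, spec.fmax_high, size=n)
    frac = (f_max - spec.fmax_low) / (spec.fmax_high - spec.fmax_low)
    S = spec.S_at_fmax_low + frac * (spec.S_at_fmax_high - spec.S_at_fmax_low)
    return CellParams.from_feedback(a0=a0, f_max=f_max, S=S, params=params)


def noise_std(
    state_Po: np.ndarray, params: ParameterSet, dt: float
) -> tuple[float, float, np.ndarray]:
    """Per-step standard deviations of the three noise channels.

    sd(eta)    = sqrt(2·k_b·T·λ/dt)
    sd(eta_a)  = sqrt(2·k_b·T_a·λ_a/dt)
    sd(delta_c)= sqrt(2·C_M²·P_o·(1 − P_o)·τ_c/(N·dt)),

    the last evaluated at the open probability at the start of the step
    (Itô convention), so it vanishes when the channels saturate.
    """
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    sd_eta = np.sqrt(2.0 * params.k_b * params.T * params.lambda_hb / dt)
    sd_eta_a = np.sqrt(2.0 * params.k_b * params.T_a * params.lambda_a / dt)
    Po = np.asarray(state_Po, dtype=float)
    sd_dc = np.sqrt(2.0 * params.C_M**2 * Po * (1.0 - Po) * params.tau_c / (params.N * dt))
    return float(sd_eta), float(sd_eta_a), sd_dc


def generate_noise(
    state_Po: np.ndarray,
    params: ParameterSet,
    dt: float,
    rng: np.random.Generator,
) -> NoiseChannels:
    """Draw one step's noise for every cell (mutually independent channels)."""
    Po = np.asarray(state_Po, dtype=float)
    if np.any((Po < 0) | (Po > 1)):
        raise ConfigurationError("P_o values must lie in [0, 1]")
    sd_eta, sd_eta_a, sd_dc = noise_std(Po, params, dt)
    n = Po.shape
    return NoiseChannels(
        eta=rng.standard_normal(n) * sd_eta,
        eta_a=rng.standard_normal(n) * sd_eta_a,
        delta_c=rng.standard_normal(n) * sd_dc,
    )
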