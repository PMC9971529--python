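"""Readouts of simulated traces: histograms, skewness, spikes, sweeps.

The damage phenomenology is quantified per bundle by

* the position histogram and its skewness — damaged-region bundles
  develop long tails in the negative direction, so skewness grows in
  magnitude with damage;
* spike detection — a spike is a large, abrupt excursion of the bundle
  position beyond a multiple of the passive thermal band;
* open-probability statistics — the histogram peak (mode) of P_o shifts
  right as damage frees the bundles to spend time with channels open.

``run_damage_sweep`` reproduces the four-condition protocol
(K_d = K, K/5, K/10, K/15) with the quenched heterogeneity held fixed
across conditions so that differences are attributable to coupling
alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .grid_coupling import DamageRegion, GridSpec
from .integrator import RunConfig, Trace, simulate
from .model_core import CellParams, ParameterSet
from .stochastics import HeterogeneitySpec

__all__ = [
    "TraceSummary",
    "SweepResult",
    "position_histogram",
    "skewness",
    "detect_spikes",
    "po_statistics",
    "summarize_trace",
    "passive_baseline_sd",
    "run_damage_sweep",
]


@dataclass(frozen=True)
class TraceSummary:
    """Per-bundle summary statistics of one recorded trace."""

    cell: tuple[int, int]
    mean_X: float
    sd_X: float
    skewness_X: float
    spike_count: int
    spike_rate: float
    mode_Po: float
    mean_Po: float


@dataclass
class SweepResult:
    """Summaries for every (damage factor, noise seed) condition.

    ``summaries[(factor, seed)]`` maps to the list of TraceSummary for
    the recorded cells of that run; ``damaged_cells``/``reference_cells``
    identify which recorded cells lie inside the damage region.
    """

    factors: list[float]
    seeds: list[int]
    damaged_cells: list[tuple[int, int]]
    reference_cells: list[tuple[int, int]]
    summaries: dict
    baseline_sd: float

    def table(self):
        """Long-format DataFrame, one row per (factor, seed, cell)."""
        import pandas as pd

        rows = []
        for (factor, seed), summs in self.summaries.items():
            for s in summs:
                rows.append(
                    {
                        "Kd_factor": factor,
                        "seed": seed,
                        "cell_row": s.cell[0],
                        "cell_col": s.cell[1],
                        "in_damage_region": s.cell in self.damaged_cells,
                        "mean_X": s.mean_X,
                        "sd_X": s.sd_X,
                        "skewness_X": s.skewness_X,
                        "spike_count": s.spike_count,
                        "spike_rate": s.spike_rate,
                        "mode_Po": s.mode_Po,
                        "mean_Po": s.mean_Po,
                    }
                )
        return pd.DataFrame(rows)

    def damaged_region_medians(self):
        """Median over damaged-region cells and seeds, per damage factor.

        Returns a DataFrame indexed by Kd_factor with columns
        spike_rate, abs_skewness, mode_Po, sd_X.
        """
        import pandas as pd

        t = self.table()
        t = t[t.in_damage_region]
        t["abs_skewness"] = t.skewness_X.abs()
        out = (
            t.groupby("Kd_factor")[["spike_rate", "abs_skewness", "mode_Po", "sd_X"]]
            .median()
            .sort_index()
        )
        return out


def position_histogram(trace_X: np.ndarray, n_bins: int = 100):
    """Histogram (counts, bin edges) of a bundle-position series."""
    x = np.asarray(trace_X, dtype=float).ravel()
    if x.size == 0:
        raise InvalidInputError("empty position series")
    counts, edges = np.histogram(x, bins=n_bins)
    return counts, edges


def skewness(series: np.ndarray) -> float:
    """Adjusted Fisher–Pearson standardized third moment."""
    from scipy import stats

    x = np.asarray(series, dtype=float).ravel()
    if x.size < 3:
        raise InvalidInputError("need at least 3 samples for skewness")
    return float(stats.skew(x, bias=False))


def detect_spikes(
    trace_X: np.ndarray,
    baseline_sd: float,
    threshold_multiple: float = 8.0,
    min_separation: float = 0.05,
    dt: float = 20e-6,
) -> np.ndarray:
    """Onset times (s) of abrupt position excursions ("spikes").

    A spike is a contiguous excursion |X − median(X)| beyond
    ``threshold_multiple × baseline_sd``, where ``baseline_sd`` is the
    thermal position noise of a passive (motors-off) bundle.  Excursions
    separated by less than ``min_separation`` seconds are merged into
    one event.  Median centering makes detection invariant to the
    model's arbitrary position offsets.

    The default multiple (8× the passive baseline) is chosen to sit
    clearly above the thermal band of *healthy, active* bundles in the
    coupled grid, whose quiescent sd is itself ≈2× the passive
    baseline; a threshold inside that band counts routine thermal
    crossings of quiescent cells as spikes and obscures the damage
    signal.
    """
    if threshold_multiple <= 0:
        raise ConfigurationError("threshold_multiple must be > 0")
    if baseline_sd <= 0:
        raise ConfigurationError("baseline_sd must be > 0")
    x = np.asarray(trace_X, dtype=float).ravel()
    dev = np.abs(x - np.median(x))
    above = dev > threshold_multiple * baseline_sd
    if not above.any():
        return np.empty(0)
    # onset indices of contiguous runs
    edges = np.diff(above.astype(np.int8))
    onsets = np.flatnonzero(edges == 1) + 1
    if above[0]:
        onsets = np.concatenate([[0], onsets])
    times = onsets * dt
    merged = [times[0]]
    # end index of each run, to merge gaps shorter than min_separation
    offsets = np.flatnonzero(edges == -1) + 1
    if above[-1]:
        offsets = np.concatenate([offsets, [len(x)]])
    for i in range(1, len(times)):
        gap = times[i] - offsets[i - 1] * dt
        if gap >= min_separation:
            merged.append(times[i])
    return np.asarray(merged)


def po_statistics(trace_Po: np.ndarray, n_bins: int = 100):
    """Histogram over [0, 1], mode (peak-bin midpoint) and mean of P_o.

    Ties between equally tall bins are broken toward the lower bin.
    Out-of-range values signal an upstream bug and are rejected.
    """
    po = np.asarray(trace_Po, dtype=float).ravel()
    if po.size == 0:
        raise InvalidInputError("empty P_o series")
    if np.any((po < 0) | (po > 1)):
        raise InvalidInputError("P_o values outside [0, 1]")
    counts, edges = np.histogram(po, bins=n_bins, range=(0.0, 1.0))
    peak = int(np.argmax(counts))  # argmax takes the first (lowest) maximal bin
    mode = 0.5 * (edges[peak] + edges[peak + 1])
    return counts, edges, float(mode), float(po.mean())


def summarize_trace(
    trace: Trace,
    cell: tuple[int, int],
    baseline_sd: float,
    threshold_multiple: float = 8.0,
    min_separation: float = 0.05,
    n_bins: int = 100,
) -> TraceSummary:
    """TraceSummary of one recorded bundle."""
    X = trace.column("X", *cell)
    Po = trace.column("P_o", *cell)
    dt_rec = float(trace.times[1] - trace.times[0])
    spikes = detect_spikes(X, baseline_sd, threshold_multiple, min_separation, dt_rec)
    _, _, mode_po, mean_po = po_statistics(Po, n_bins)
    duration = trace.duration if trace.duration > 0 else np.nan
    return TraceSummary(
        cell=cell,
        mean_X=float(X.mean()),
        sd_X=float(X.std()),
        skewness_X=skewness(X),
        spike_count=len(spikes),
        spike_rate=len(spikes) / duration,
        mode_Po=mode_po,
        mean_Po=mean_po,
    )


def passive_baseline_sd(
    run: RunConfig,
    grid: GridSpec,
    damage: DamageRegion | None = None,
    params: ParameterSet | None = None,
    aggregate: str = "median",
) -> float | np.ndarray:
    """Thermal position noise of the motors-off grid (the passive baseline).

    Runs the identical configuration with every motor force set to zero
    and returns the per-bundle sd(X), aggregated by ``aggregate``
    ("median", "none" for the per-cell array).  This is the yardstick
    against which both quiescence (amplitude death) and restored
    motility are measured.
    """
    if params is None:
        params = ParameterSet()
    n = grid.n_cells
    passive = CellParams.from_feedback(
        a0=np.ones(n), f_max=np.zeros(n), S=np.zeros(n), params=params
    )
    tr = simulate(run, grid, damage=damage, params=params, cells_override=passive)
    sd = tr.X.std(axis=0)
    if aggregate == "median":
        return float(np.median(sd))
    if aggregate == "none":
        return sd
    raise ConfigurationError(f"unknown aggregate {aggregate!r}")


def run_damage_sweep(
    run: RunConfig,
    grid: GridSpec,
    damage: DamageRegion,
    het: HeterogeneitySpec,
    params: ParameterSet | None = None,
    factors: tuple[float, ...] = (1.0, 5.0, 10.0, 15.0),
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    reference_cells: list[tuple[int, int]] | None = None,
    threshold_multiple: float = 8.0,
    min_separation: float = 0.05,
) -> SweepResult:
    """Paired sweep over damage levels K_d = K/factor.

    The heterogeneity seed (and hence every bundle's a0, f_max, S) is
    shared across factors and noise seeds, so condition differences are
    attributable to the coupling change alone.  Spike detection uses the
    passive baseline of the healthy grid, computed once.

    Records all damaged-region cells plus a spread of healthy reference
    cells (default: four cells at increasing distance from the region).
    """
    if params is None:
        params = ParameterSet()
    if any(f < 1 for f in factors):
        raise ConfigurationError("damage factors must be >= 1")
    if len(seeds) < 1:
        raise ConfigurationError("need at least one noise seed")
    damage.validate_within(grid)

    damaged_cells = [
        (r, c)
        for r in range(damage.row_start, damage.row_stop + 1)
        for c in range(damage.col_start, damage.col_stop + 1)
    ]
    if reference_cells is None:
        # healthy cells spread from near the region to the far corner
        rr, cc = grid.n_rows - 1, grid.n_cols - 1
        mid_r, mid_c = grid.n_rows // 2, grid.n_cols // 2
        reference_cells = [
            (min(damage.row_stop + 2, rr), min(damage.col_stop + 2, cc)),
            (mid_r, mid_c),
            (rr, mid_c),
            (rr, cc),
        ]
        reference_cells = [c for c in reference_cells if c not in damaged_cells]
    recorded = damaged_cells + [c for c in reference_cells if c not in damaged_cells]

    base_run = replace(run, recorded_cells=recorded)
    baseline = passive_baseline_sd(base_run, grid, damage=None, params=params)

    summaries = {}
    for factor in factors:
        grid_f = replace(grid, K_d=grid.K / factor)
        for seed in seeds:
            run_fs = replace(base_run, seed=seed)
            tr = simulate(run_fs, grid_f, damage=damage, het=het, params=params)
            summaries[(factor, seed)] = [
                summarize_trace(tr, cell, baseline, threshold_multiple, min_separation)
                for cell in recorded
            ]
    return SweepResult(
        factors=sorted(factors),
        seeds=list(seeds),
        damaged_cells=damaged_cells,
        reference_cells=list(reference_cells),
        summaries=summaries,
        baseline_sd=baseline,
    )
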