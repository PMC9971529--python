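"""Figure helpers: offset trace panels and histogram grids.

Conventions follow the standard presentation of damage sweeps: one
panel per damage level, bundle-position traces vertically offset for
clarity with the damaged-region focal trace drawn in black, and
histogram grids of position or open probability.
"""

from __future__ import annotations

import numpy as np

from .analysis import po_statistics, position_histogram
from .integrator import Trace

__all__ = ["plot_traces", "plot_histogram_grid"]


def plot_traces(
    traces: list[Trace],
    cells: list[tuple[int, int]],
    focal: tuple[int, int] | None = None,
    labels: list[str] | None = None,
    offset: float = 80e-9,
    ax=None,
):
    """Stacked position traces, one panel per condition.

    ``traces`` is one Trace per condition (e.g. per damage level);
    ``cells`` the bundles to draw in every panel.  The ``focal`` cell
    (damaged region) is drawn in black on top.  Arbitrary vertical
    offsets (``offset`` apart) are added for clarity.
    """
    import matplotlib.pyplot as plt

    n = len(traces)
    if ax is None:
        _, axes = plt.subplots(n, 1, figsize=(8, 2.2 * n), sharex=True, squeeze=False)
        axes = axes[:, 0]
    else:
        axes = np.atleast_1d(ax)
    for panel, trace in zip(axes, traces):
        for i, cell in enumerate(cells):
            x = trace.column("X", *cell)
            x = x - np.median(x) + i * offset
            is_focal = focal is not None and tuple(cell) == tuple(focal)
            panel.plot(
                trace.times, x * 1e9,
                color="black" if is_focal else None,
                lw=1.0 if is_focal else 0.6,
                zorder=3 if is_focal else 2,
            )
        panel.set_ylabel("X (nm)")
    if labels:
        for panel, lab in zip(axes, labels):
            panel.set_title(lab, fontsize=9, loc="left")
    axes[-1].set_xlabel("time (s)")
    return axes


def plot_histogram_grid(
    traces: list[Trace],
    cell: tuple[int, int],
    quantity: str = "X",
    labels: list[str] | None = None,
    n_bins: int = 100,
    axes=None,
):
    """Histograms of one bundle's position or P_o, one panel per condition."""
    import matplotlib.pyplot as plt

    n = len(traces)
    if axes is None:
        _, axes = plt.subplots(1, n, figsize=(2.6 * n, 2.4), squeeze=False)
        axes = axes[0]
    for panel, trace in zip(np.atleast_1d(axes), traces):
        if quantity == "X":
            x = trace.column("X", *cell)
            counts, edges = position_histogram(x - np.median(x), n_bins)
            panel.stairs(counts, edges * 1e9)
            panel.set_xlabel("X (nm)")
        elif quantity == "Po":
            counts, edges, _, _ = po_statistics(trace.column("P_o", *cell), n_bins)
            panel.stairs(counts, edges)
            panel.set_xlabel("$P_o$")
        else:
            raise ValueError(f"unknown quantity {quantity!r}")
        panel.set_yscale("log")
    if labels:
        for panel, lab in zip(np.atleast_1d(axes), labels):
            panel.set_title(lab, fontsize=9, loc="left")
    return axes
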