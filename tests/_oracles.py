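"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the closed forms in the package: travel time by
explicit time stepping, labeled coverage by discrete-event simulation of
individual polymerases on an initiation-time grid, and interval counting
by per-base expansion.
"""

from __future__ import annotations

import numpy as np


def travel_time_stepping(segments, x_target: float, dt: float = 0.01) -> float:
    """Time-step a single polymerase through the rate field until x_target."""
    x, t = 0.0, 0.0
    edges = np.cumsum([0.0] + [s[0] for s in segments])
    rates = [s[1] * 1e3 for s in segments]  # bp/min
    while x < x_target:
        seg = int(np.searchsorted(edges, x, side="right")) - 1
        seg = min(seg, len(rates) - 1)
        x += rates[seg] * dt
        t += dt
    return t


def discrete_event_coverage(init, elong, window, bin_size: int, gene_length: float,
                            dt: float = 0.01) -> np.ndarray:
    """Expected labeled passages per bin by enumerating polymerases started on
    a dt grid, each weighted by I(t0) * dt; a bin is credited when the
    polymerase transcribes its center inside the labeling window."""
    ws, we = window
    n = int(np.ceil(gene_length / bin_size))
    edges = np.minimum(np.arange(n + 1, dtype=float) * bin_size, gene_length)
    centers = (edges[:-1] + edges[1:]) / 2.0
    tau = np.asarray(elong.travel_time(centers), dtype=float)
    t0_lo = ws - float(tau.max()) - dt
    grid = np.arange(t0_lo, we, dt) + dt / 2.0
    weights = np.asarray(init.rate_at(grid), dtype=float) * dt
    out = np.empty(n)
    arrive = grid[None, :] + tau[:, None]
    mask = (arrive >= ws) & (arrive <= we)
    out = (mask * weights[None, :]).sum(axis=1)
    return out


def per_base_count(bin_values: np.ndarray, bin_size: int, start: int, end: int) -> float:
    """Reads in [start, end) by spreading each bin's count uniformly over its
    bases and summing base by base."""
    per_base = np.repeat(np.asarray(bin_values, dtype=float) / bin_size, bin_size)
    start = max(0, start)
    end = min(len(per_base), end)
    if end <= start:
        return 0.0
    return float(per_base[start:end].sum())
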