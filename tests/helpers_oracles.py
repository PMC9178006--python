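"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's own code paths: Benjamini-Hochberg
is computed from its definition, the broad-peak oracle enumerates tiles
and merges by scanning, and tile coverage is found by trying every tile.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def bh_adjust_oracle(pvals: np.ndarray) -> np.ndarray:
    """BH q-values straight from the definition (step-up, cumulative min)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q


def covering_tiles_oracle(pos: int, n_tiles: int, binsize: int, stepsize: int) -> list[int]:
    """All tiles containing `pos`, found by trying every tile."""
    return [
        k
        for k in range(n_tiles)
        if k * stepsize <= pos < k * stepsize + binsize
    ]


def broad_peaks_oracle(
    counts: np.ndarray,
    values: np.ndarray,
    chrom_length: int,
    binsize: int,
    stepsize: int,
    lam: float,
    q_threshold: float,
    merge_gap: int,
    min_rpkm: float,
    min_width: int,
) -> list[tuple[int, int, float, float]]:
    """Enumerate-threshold-merge-filter peak calling on one chromosome.

    Returns (start, end, mean_rpkm, min_q) tuples after the quality filter.
    """
    n = len(counts)
    p = np.array([stats.poisson.sf(c - 1, lam) for c in counts])
    q = bh_adjust_oracle(p)
    sig = [k for k in range(n) if q[k] <= q_threshold]
    peaks = []
    group: list[int] = []
    for k in sig:
        if group and k * stepsize - min(group[-1] * stepsize + binsize, chrom_length) > merge_gap:
            peaks.append(group)
            group = []
        group = group + [k]
    if group:
        peaks.append(group)
    out = []
    for g in peaks:
        start = g[0] * stepsize
        end = min(max(k * stepsize + binsize for k in g), chrom_length)
        mean_rpkm = float(np.mean([values[k] for k in g]))
        min_q = float(min(q[k] for k in g))
        if mean_rpkm >= min_rpkm and end - start >= min_width:
            out.append((start, end, mean_rpkm, min_q))
    return out
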