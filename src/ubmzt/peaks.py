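"""Broad-domain peak calling on normalized tracks.

Each tile's raw count is tested against a global background rate (a Poisson
upper tail, with the rate estimated from random-region tiles of the same
track, so per-sample efficiency cancels).  Benjamini-Hochberg control is
applied across all tiles; significant tiles are merged into broad domains
when separated by at most ``merge_gap`` bp, and domains failing the quality
filters (mean RPKM < 1 or width < 800 bp by default) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_model import GenomeAnnotation, GenomicInterval, classify_interval
from .signal import SignalTrack, tiles_in_regions

__all__ = [
    "Peak",
    "PeakSet",
    "call_broad_peaks",
    "filter_peaks",
    "annotate_peaks",
    "write_peaks_bed",
]

CATEGORIES = ("TSS", "TES", "gene body", "intergenic")


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    mean_rpkm: float
    q_value: float

    @property
    def width(self) -> int:
        return self.interval.width


@dataclass
class PeakSet:
    sample_id: str
    peaks: list[Peak]

    def __len__(self) -> int:
        return len(self.peaks)


def call_broad_peaks(
    track: SignalTrack,
    background_regions: Sequence[GenomicInterval],
    q_threshold: float = 0.05,
    merge_gap: int = 1000,
) -> PeakSet:
    """Poisson/BH broad caller against the track's own background rate.

    The background rate is the mean raw tile count over tiles whose
    midpoints fall in ``background_regions``.  Tiles with BH-adjusted
    upper-tail p <= ``q_threshold`` are merged whenever the gap between
    their (binsize-wide) intervals is <= ``merge_gap``; each merged run
    becomes one peak carrying the mean RPKM of its tiles and their
    minimum q.
    """
    grid = track.grid
    mask = tiles_in_regions(grid, background_regions)
    bg_counts = np.concatenate([track.counts[c][mask[c]] for c in grid.chroms])
    if len(bg_counts) == 0:
        raise ValueError("no tiles fall inside the background regions")
    lam = float(bg_counts.mean())
    if lam <= 0:
        raise ValueError("background rate is zero; cannot call peaks")

    all_counts = track.concat_counts()
    pvals = stats.poisson.sf(all_counts - 1, lam)  # P(X >= count)
    qvals = multipletests(pvals, method="fdr_bh")[1]

    sizes = dict(grid.chrom_sizes)
    peaks: list[Peak] = []
    offset = 0
    for chrom in grid.chroms:
        n = grid.n_tiles(chrom)
        q = qvals[offset : offset + n]
        vals = track.values[chrom]
        sig = np.flatnonzero(q <= q_threshold)
        offset += n
        if len(sig) == 0:
            continue
        starts = sig * grid.stepsize
        ends = np.minimum(starts + grid.binsize, sizes[chrom])
        run = [0]
        for i in range(1, len(sig)):
            if starts[i] - ends[run[-1]] <= merge_gap:
                run.append(i)
            else:
                peaks.append(_emit(chrom, sig[run], starts, ends, run, vals, q))
                run = [i]
        peaks.append(_emit(chrom, sig[run], starts, ends, run, vals, q))
    return PeakSet(track.sample.sample_id, peaks)


def _emit(chrom, tile_idx, starts, ends, run, vals, q) -> Peak:
    lo = int(starts[run[0]])
    hi = int(max(ends[i] for i in run))
    return Peak(
        GenomicInterval(chrom, lo, hi),
        mean_rpkm=float(np.mean(vals[tile_idx])),
        q_value=float(np.min(q[tile_idx])),
    )


def filter_peaks(ps: PeakSet, min_rpkm: float = 1.0, min_width: int = 800) -> PeakSet:
    """Discard low-quality peaks (mean RPKM below 1 or width below 800 bp)."""
    kept = [p for p in ps.peaks if p.mean_rpkm >= min_rpkm and p.width >= min_width]
    return PeakSet(ps.sample_id, kept)


def annotate_peaks(ps: PeakSet, ann: GenomeAnnotation, flank: int = 2000) -> dict[str, int]:
    """Count peaks per genomic category (TSS / TES / gene body / intergenic)."""
    counts = {c: 0 for c in CATEGORIES}
    for p in ps.peaks:
        counts[classify_interval(p.interval, ann, flank)] += 1
    return counts


def write_peaks_bed(ps: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(ps.peaks):
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\tpeak{i}\t{p.mean_rpkm:.6g}\t{p.q_value:.6g}\n"
            )
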