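"""Strand-aware TSS-centered average signal profiles (metaplots).

For each gene in a set, normalized track values are sampled at fixed
offsets from the TSS; for '-'-strand genes the offset axis is flipped so
that positive offsets always point downstream of transcription.  Values at
a genomic position are the mean of all sliding tiles covering it.
Per-gene positions that fall off the chromosome are dropped and the
per-offset denominator tracks how many genes contributed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import GenomeAnnotation
from .signal import SignalTrack

__all__ = ["MetaProfile", "tss_profile", "compare_profiles"]


@dataclass
class MetaProfile:
    name: str
    offsets: np.ndarray   # bp relative to TSS, symmetric around 0
    mean: np.ndarray      # mean normalized signal per offset
    n: np.ndarray         # genes contributing per offset

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"offset": self.offsets, "mean": self.mean, "n": self.n}
        ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _value_at(track: SignalTrack, chrom: str, pos: np.ndarray) -> np.ndarray:
    """Mean of covering-tile values at each position (NaN when off-chromosome)."""
    grid = track.grid
    vals = track.values[chrom]
    n = len(vals)
    length = dict(grid.chrom_sizes)[chrom]
    n_off = -(-grid.binsize // grid.stepsize)
    out = np.full(len(pos), np.nan)
    inside = (pos >= 0) & (pos < length)
    p = pos[inside]
    acc = np.zeros(len(p))
    cnt = np.zeros(len(p))
    k_hi = p // grid.stepsize
    for d in range(n_off):
        k = k_hi - d
        ok = (k >= 0) & (k < n) & (k * grid.stepsize + grid.binsize > p)
        acc[ok] += vals[k[ok]]
        cnt[ok] += 1
    res = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    out[inside] = res
    return out


def tss_profile(
    track: SignalTrack,
    genes: Sequence[str] | frozenset[str],
    ann: GenomeAnnotation,
    window: int = 5000,
    step: int | None = None,
    name: str = "gene_set",
) -> MetaProfile:
    """Average normalized signal around the TSS of a gene set."""
    genes = sorted(genes)
    if not genes:
        raise ValueError("gene set is empty")
    step = step or track.grid.stepsize
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    offsets = np.arange(-window, window + step, step, dtype=np.int64)
    total = np.zeros(len(offsets))
    count = np.zeros(len(offsets), dtype=np.int64)
    for gid in genes:
        g = ann.genes[gid]
        sign = 1 if g.strand == "+" else -1
        pos = g.tss + sign * offsets
        v = _value_at(track, g.chrom, pos)
        ok = ~np.isnan(v)
        total[ok] += v[ok]
        count += ok
    mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return MetaProfile(name, offsets, mean, count)


def compare_profiles(
    profile_set: MetaProfile, profile_random: MetaProfile
) -> tuple[np.ndarray, float]:
    """Per-offset difference (set - random) and the ratio at the TSS."""
    if not np.array_equal(profile_set.offsets, profile_random.offsets):
        raise ValueError("profiles were computed on different offset grids")
    diff = profile_set.mean - profile_random.mean
    at0 = int(np.flatnonzero(profile_set.offsets == 0)[0])
    denom = profile_random.mean[at0]
    ratio = float(profile_set.mean[at0] / denom) if denom > 0 else np.nan
    return diff, ratio
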