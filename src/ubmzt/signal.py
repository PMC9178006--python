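"""Binned signal tracks: deduplication, sliding-window counting, RPKM scaling
and background-anchored cross-sample normalization.

The normalization exploits the high uniform background of carrier-assisted
low-input ChIP: because the background samples the genome evenly, its level
in randomly drawn regions is proportional to each sample's global efficiency
and can anchor tracks onto a common scale without spike-ins.  The statistic
is a trimmed mean of RPKM over tiles whose midpoints fall inside the random
regions, robust to the minority of regions that overlap true signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_model import GenomeAnnotation, GenomicInterval
from .synthetic_data import ReadSet, SampleInfo

__all__ = [
    "BinGrid",
    "SignalTrack",
    "deduplicate",
    "bin_counts",
    "rpkm",
    "make_track",
    "background_normalize",
    "track_correlation",
    "tiles_in_regions",
    "write_bedgraph",
    "read_bedgraph_values",
    "write_sample_sheet",
]

TRIM_FRACTION = 0.2  # trimmed from each tail of the background distribution


@dataclass(frozen=True)
class BinGrid:
    """Sliding tiles of `binsize` bp placed every `stepsize` bp per chromosome.

    Tile k on a chromosome covers [k*stepsize, k*stepsize + binsize); tiles
    exist while their start lies inside the chromosome, so neighbouring
    tiles overlap whenever stepsize < binsize.
    """

    chrom_sizes: tuple[tuple[str, int], ...]
    binsize: int = 1000
    stepsize: int = 200

    def __post_init__(self) -> None:
        if self.stepsize <= 0 or self.binsize <= 0:
            raise ValueError("binsize and stepsize must be > 0")
        if self.stepsize > self.binsize:
            raise ValueError("stepsize must be <= binsize")

    @classmethod
    def from_annotation(cls, ann: GenomeAnnotation, binsize: int = 1000, stepsize: int = 200) -> "BinGrid":
        return cls(tuple(ann.chromosomes.items()), binsize, stepsize)

    @property
    def chroms(self) -> list[str]:
        return [c for c, _ in self.chrom_sizes]

    def n_tiles(self, chrom: str) -> int:
        length = dict(self.chrom_sizes)[chrom]
        return int(np.ceil(length / self.stepsize))

    def tile_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_tiles(chrom), dtype=np.int64) * self.stepsize

    def covering_tiles(self, chrom: str, pos: int) -> np.ndarray:
        """Indices of tiles whose interval contains `pos`."""
        k_hi = pos // self.stepsize
        k_lo = max(0, (pos - self.binsize) // self.stepsize + 1)
        k_hi = min(k_hi, self.n_tiles(chrom) - 1)
        if k_hi < k_lo:
            return np.empty(0, dtype=np.int64)
        return np.arange(k_lo, k_hi + 1, dtype=np.int64)


@dataclass
class SignalTrack:
    """Per-tile counts and RPKM values on a BinGrid for one sample."""

    grid: BinGrid
    counts: dict[str, np.ndarray]
    values: dict[str, np.ndarray]
    sample: SampleInfo
    total_reads: int
    background_scale: float = 1.0

    def concat_values(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.grid.chroms])

    def concat_counts(self) -> np.ndarray:
        return np.concatenate([self.counts[c] for c in self.grid.chroms])


def deduplicate(rs: ReadSet) -> ReadSet:
    """Drop PCR duplicates: at most one read per (chrom, start, end, strand)."""
    df = rs.reads.drop_duplicates(subset=["chrom", "start", "end", "strand"])
    df = df.sort_values(["chrom", "start", "end", "strand"], kind="stable").reset_index(drop=True)
    return ReadSet(rs.sample, df)


def bin_counts(rs: ReadSet, grid: BinGrid) -> dict[str, np.ndarray]:
    """Count reads per tile, assigning each read to every tile covering its midpoint."""
    n_off = -(-grid.binsize // grid.stepsize)  # tiles covering a point
    out: dict[str, np.ndarray] = {}
    sizes = dict(grid.chrom_sizes)
    groups = dict(tuple(rs.reads.groupby("chrom", observed=True)))
    for chrom in grid.chroms:
        n = grid.n_tiles(chrom)
        counts = np.zeros(n, dtype=np.int64)
        g = groups.get(chrom)
        if g is not None and len(g):
            mids = ((g["start"].to_numpy() + g["end"].to_numpy()) // 2).astype(np.int64)
            mids = mids[(mids >= 0) & (mids < sizes[chrom])]
            k_hi = mids // grid.stepsize
            for d in range(n_off):
                k = k_hi - d
                ok = (k >= 0) & (k < n) & (k * grid.stepsize + grid.binsize > mids)
                np.add.at(counts, k[ok], 1)
        out[chrom] = counts
    return out


def rpkm(counts: dict[str, np.ndarray], grid: BinGrid, total_reads: int) -> dict[str, np.ndarray]:
    """Reads per kilobase (of tile) per million mapped reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    scale = 1.0 / (grid.binsize / 1000.0) / (total_reads / 1e6)
    return {c: v * scale for c, v in counts.items()}


def make_track(rs: ReadSet, grid: BinGrid, deduplicated: bool = False) -> SignalTrack:
    """Deduplicate (unless already done), bin and RPKM-scale one sample."""
    if not deduplicated:
        rs = deduplicate(rs)
    counts = bin_counts(rs, grid)
    values = rpkm(counts, grid, rs.total)
    return SignalTrack(grid, counts, values, rs.sample, rs.total)


def tiles_in_regions(grid: BinGrid, regions: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    """Boolean mask per chromosome: tiles whose midpoints fall in the regions."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out = {}
    for chrom in grid.chroms:
        mids = grid.tile_starts(chrom) + grid.binsize // 2
        mask = np.zeros(len(mids), dtype=bool)
        rs = by_chrom.get(chrom, [])
        if rs:
            starts = np.array(sorted(r.start for r in rs))
            # merge overlapping regions
            ends = np.array([r.end for r in sorted(rs, key=lambda r: r.start)])
            merged_s, merged_e = [starts[0]], [ends[0]]
            for s, e in zip(starts[1:], ends[1:]):
                if s <= merged_e[-1]:
                    merged_e[-1] = max(merged_e[-1], e)
                else:
                    merged_s.append(s)
                    merged_e.append(e)
            ms = np.array(merged_s)
            me = np.array(merged_e)
            j = np.searchsorted(ms, mids, side="right") - 1
            ok = j >= 0
            mask[ok] = mids[ok] < me[j[ok]]
        out[chrom] = mask
    return out


def _background_level(track: SignalTrack, mask: dict[str, np.ndarray]) -> float:
    vals = np.concatenate([track.values[c][mask[c]] for c in track.grid.chroms])
    if len(vals) == 0:
        raise ValueError("no tiles fall inside the background regions")
    return float(stats.trim_mean(vals, TRIM_FRACTION))


def background_normalize(
    tracks: Sequence[SignalTrack], regions: Sequence[GenomicInterval]
) -> list[SignalTrack]:
    """Rescale tracks so their trimmed-mean background over `regions` matches.

    The first track is the reference; each track is multiplied by
    (reference background / own background) and the applied factor is
    accumulated in ``background_scale``.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks to normalize")
    grid = tracks[0].grid
    for t in tracks[1:]:
        if t.grid != grid:
            raise ValueError("all tracks must share one grid")
    if not regions:
        raise ValueError("regions must be non-empty")
    mask = tiles_in_regions(grid, regions)
    levels = [_background_level(t, mask) for t in tracks]
    if any(l <= 0 for l in levels):
        raise ValueError("a track has zero background level; cannot normalize")
    ref = levels[0]
    out = []
    for t, level in zip(tracks, levels):
        factor = ref / level
        out.append(
            SignalTrack(
                grid=t.grid,
                counts=t.counts,
                values={c: v * factor for c, v in t.values.items()},
                sample=t.sample,
                total_reads=t.total_reads,
                background_scale=t.background_scale * factor,
            )
        )
    return out


def track_correlation(
    a: SignalTrack,
    b: SignalTrack,
    scope: str = "genome",
    regions: Sequence[GenomicInterval] | None = None,
) -> float:
    """Pearson correlation of tile values, genome-wide or within regions."""
    if a.grid != b.grid:
        raise ValueError("tracks must share one grid")
    if scope == "genome":
        x, y = a.concat_values(), b.concat_values()
    elif scope == "promoters":
        if regions is None:
            raise ValueError("scope='promoters' requires regions")
        mask = tiles_in_regions(a.grid, regions)
        x = np.concatenate([a.values[c][mask[c]] for c in a.grid.chroms])
        y = np.concatenate([b.values[c][mask[c]] for c in a.grid.chroms])
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance track; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


# -- bedGraph export (decimated to non-overlapping step windows) -----------


def _decimated(track: SignalTrack, chrom: str) -> np.ndarray:
    """Mean of covering tiles for each non-overlapping stepsize window."""
    grid = track.grid
    vals = track.values[chrom]
    n = len(vals)
    n_off = -(-grid.binsize // grid.stepsize)
    out = np.zeros(n)
    cnt = np.zeros(n)
    for d in range(n_off):
        # tile k covers windows k .. k + n_off - 1 (clipped)
        sl = slice(d, n)
        out[sl] += vals[: n - d]
        cnt[sl] += 1
    return out / cnt


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    sizes = dict(track.grid.chrom_sizes)
    step = track.grid.stepsize
    with open(path, "w") as fh:
        for chrom in track.grid.chroms:
            vals = _decimated(track, chrom)
            for k, v in enumerate(vals):
                start = k * step
                end = min(start + step, sizes[chrom])
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


def read_bedgraph_values(path: str | Path) -> dict[str, np.ndarray]:
    per_chrom: dict[str, list[float]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, _s, _e, v = line.split("\t")
        per_chrom.setdefault(chrom, []).append(float(v))
    return {c: np.array(v) for c, v in per_chrom.items()}


def write_sample_sheet(tracks: Sequence[SignalTrack], path: str | Path) -> None:
    rows = [
        {
            "sample_id": t.sample.sample_id,
            "stage": t.sample.stage,
            "genotype": t.sample.genotype,
            "mark": t.sample.mark,
            "replicate": t.sample.replicate,
            "total_reads": t.total_reads,
            "background_scale": t.background_scale,
        }
        for t in tracks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
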