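"""Genome and gene-annotation data model.

Coordinates are 0-based, half-open (BED convention) throughout the package.
The transcription start site (TSS) of a '+'-strand gene is its ``start``;
for a '-'-strand gene it is ``end - 1``, i.e. the last base inside the
half-open interval.  Promoters are the +/-`flank` bp window around the TSS
(default 2 kb), clipped to chromosome bounds.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Chromosome",
    "GeneRecord",
    "GenomicInterval",
    "PromoterRegion",
    "GenomeAnnotation",
    "load_annotation",
    "write_annotation",
    "load_chrom_sizes",
    "write_chrom_sizes",
    "promoter_of",
    "classify_interval",
    "sample_random_regions",
    "sample_random_genes",
    "read_bed_intervals",
    "write_bed_intervals",
]

DEFAULT_FLANK = 2000


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise AnnotationError(f"chromosome {self.name!r}: length must be > 0")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end)."""

    chrom: str
    start: int
    end: int
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.start < 0:
            raise AnnotationError(f"interval on {self.chrom}: negative start")
        if self.strand is not None and self.strand not in ("+", "-"):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: require 0 <= start < end, got "
                f"[{self.start}, {self.end})"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class PromoterRegion:
    gene_id: str
    interval: GenomicInterval


class GenomeAnnotation:
    """Chromosome sizes plus strand-aware single-TSS gene records."""

    def __init__(
        self,
        chromosomes: Iterable[Chromosome] | Mapping[str, int],
        genes: Iterable[GeneRecord] = (),
    ):
        if isinstance(chromosomes, Mapping):
            chromosomes = [Chromosome(n, l) for n, l in chromosomes.items()]
        self.chromosomes: dict[str, int] = {}
        for c in chromosomes:
            if c.name in self.chromosomes:
                raise AnnotationError(f"duplicate chromosome {c.name!r}")
            self.chromosomes[c.name] = c.length
        self.genes: dict[str, GeneRecord] = {}
        for g in genes:
            self.add_gene(g)
        self._index_cache: dict[str, "_ChromIndex"] | None = None

    def add_gene(self, gene: GeneRecord) -> None:
        if gene.gene_id in self.genes:
            raise AnnotationError(f"duplicate gene id {gene.gene_id!r}")
        length = self.chromosomes.get(gene.chrom)
        if length is None:
            raise AnnotationError(f"gene {gene.gene_id}: unknown chromosome {gene.chrom!r}")
        if gene.end > length:
            raise AnnotationError(
                f"gene {gene.gene_id}: end {gene.end} exceeds {gene.chrom} length {length}"
            )
        self.genes[gene.gene_id] = gene
        self._index_cache = None

    # -- convenience -------------------------------------------------------

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chromosomes)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def chrom_length(self, chrom: str) -> int:
        try:
            return self.chromosomes[chrom]
        except KeyError:
            raise AnnotationError(f"unknown chromosome {chrom!r}") from None

    def promoters(self, flank: int = DEFAULT_FLANK) -> dict[str, PromoterRegion]:
        return {gid: promoter_of(g, self.chrom_length(g.chrom), flank) for gid, g in self.genes.items()}

    def _indexes(self) -> dict[str, "_ChromIndex"]:
        if self._index_cache is None:
            self._index_cache = _build_indexes(self)
        return self._index_cache


# -- per-chromosome lookup structures -------------------------------------


@dataclass
class _ChromIndex:
    tss: np.ndarray        # sorted TSS positions
    tes: np.ndarray        # sorted TES positions
    body_starts: np.ndarray  # merged gene-body intervals, sorted
    body_ends: np.ndarray


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e)
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s), np.asarray(out_e)


def _build_indexes(ann: GenomeAnnotation) -> dict[str, _ChromIndex]:
    per_chrom: dict[str, list[GeneRecord]] = {c: [] for c in ann.chromosomes}
    for g in ann.genes.values():
        per_chrom[g.chrom].append(g)
    out = {}
    for chrom, genes in per_chrom.items():
        tss = np.sort(np.array([g.tss for g in genes], dtype=np.int64))
        tes = np.sort(np.array([g.tes for g in genes], dtype=np.int64))
        starts = np.array([g.start for g in genes], dtype=np.int64)
        ends = np.array([g.end for g in genes], dtype=np.int64)
        ms, me = _merge_intervals(starts, ends)
        out[chrom] = _ChromIndex(tss=tss, tes=tes, body_starts=ms, body_ends=me)
    return out


def _near_sorted(positions: np.ndarray, point: int, flank: int) -> bool:
    """True if any position p satisfies point in [p - flank, p + flank)."""
    if len(positions) == 0:
        return False
    i = int(np.searchsorted(positions, point))
    for j in (i - 1, i):
        if 0 <= j < len(positions):
            p = int(positions[j])
            if p - flank <= point < p + flank:
                return True
    return False


# -- operations ------------------------------------------------------------


def promoter_of(gene: GeneRecord, chrom_length: int, flank: int = DEFAULT_FLANK) -> PromoterRegion:
    """Promoter window [tss - flank, tss + flank) clipped to the chromosome."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    start = max(0, gene.tss - flank)
    end = min(chrom_length, gene.tss + flank)
    return PromoterRegion(gene.gene_id, GenomicInterval(gene.chrom, start, end, gene.strand))


def classify_interval(
    iv: GenomicInterval, ann: GenomeAnnotation, flank: int = DEFAULT_FLANK
) -> str:
    """Classify an interval by its midpoint as TSS, TES, gene body or intergenic.

    Single-label assignment with precedence TSS > TES > gene body; the
    TSS/TES zones are the +/-`flank` bp windows around the respective site.
    """
    if iv.chrom not in ann.chromosomes:
        raise AnnotationError(f"unknown chromosome {iv.chrom!r}")
    idx = ann._indexes()[iv.chrom]
    mid = iv.midpoint
    if _near_sorted(idx.tss, mid, flank):
        return "TSS"
    if _near_sorted(idx.tes, mid, flank):
        return "TES"
    if len(idx.body_starts):
        j = int(np.searchsorted(idx.body_starts, mid, side="right")) - 1
        if j >= 0 and mid < idx.body_ends[j]:
            return "gene body"
    return "intergenic"


def sample_random_regions(
    ann: GenomeAnnotation, n: int, length: int = 5000, seed: int | np.random.Generator = 0
) -> list[GenomicInterval]:
    """Sample `n` fixed-length intervals uniformly over the genome.

    Start positions are uniform over the concatenated genome so chromosomes
    are visited proportionally to their (length - region length).
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    shortest = min(ann.chromosomes.values())
    if length > shortest:
        raise ValueError(
            f"region length {length} exceeds shortest chromosome ({shortest} bp)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = list(ann.chromosomes)
    avail = np.array([ann.chromosomes[c] - length + 1 for c in chroms], dtype=np.float64)
    probs = avail / avail.sum()
    which = rng.choice(len(chroms), size=n, p=probs)
    out = []
    for k in which:
        start = int(rng.integers(0, avail[k]))
        out.append(GenomicInterval(chroms[k], start, start + length))
    return out


def sample_random_genes(
    ann: GenomeAnnotation, n: int, seed: int | np.random.Generator = 0
) -> set[str]:
    """Uniform sample of `n` gene ids without replacement."""
    ids = ann.gene_ids
    if n > len(ids):
        raise ValueError(f"cannot sample {n} genes from {len(ids)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    picked = rng.choice(len(ids), size=n, replace=False)
    return {ids[int(i)] for i in picked}


# -- I/O -------------------------------------------------------------------


def load_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise AnnotationError(f"{path}:{lineno}: expected 2 tab-separated columns")
        sizes[parts[0]] = int(parts[1])
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\t{l}\n" for c, l in sizes.items()))


def load_annotation(
    path: str | Path,
    chrom_sizes: Mapping[str, int] | str | Path,
    fmt: str = "tsv",
) -> GenomeAnnotation:
    """Read a gene table (5-column TSV or BED12) into a GenomeAnnotation.

    The TSV columns are gene_id, chrom, strand, start, end with 0-based,
    half-open coordinates.  BED12 uses columns chrom, start, end, name,
    score, strand; blocks are ignored (one TSS per gene).
    """
    if not isinstance(chrom_sizes, Mapping):
        chrom_sizes = load_chrom_sizes(chrom_sizes)
    ann = GenomeAnnotation(dict(chrom_sizes))
    fmt = fmt.lower()
    if fmt not in ("tsv", "bed12"):
        raise ValueError(f"unknown annotation format {fmt!r}")
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        try:
            if fmt == "tsv":
                if len(parts) < 5:
                    raise AnnotationError("expected 5 columns (gene_id chrom strand start end)")
                gid, chrom, strand = parts[0], parts[1], parts[2]
                start, end = int(parts[3]), int(parts[4])
            else:
                if len(parts) < 6:
                    raise AnnotationError("expected >= 6 BED columns")
                chrom, gid, strand = parts[0], parts[3], parts[5]
                start, end = int(parts[1]), int(parts[2])
            ann.add_gene(GeneRecord(gid, chrom, strand, start, end))
        except (ValueError, AnnotationError) as exc:
            raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return ann


def write_annotation(ann: GenomeAnnotation, path: str | Path) -> None:
    """Write the gene table as a 5-column TSV (gene_id chrom strand start end)."""
    with open(path, "w") as fh:
        for g in ann.genes.values():
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.start}\t{g.end}\n")


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED6 (or BED3) rows as GenomicIntervals."""
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise AnnotationError(f"{path}:{lineno}: expected >= 3 BED columns")
        strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else None
        out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_bed_intervals(
    ivs: Sequence[GenomicInterval], path: str | Path, names: Sequence[str] | None = None
) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            name = names[i] if names is not None else f"iv{i}"
            strand = iv.strand or "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")
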