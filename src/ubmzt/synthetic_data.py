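"""Synthetic study generator with planted ground truth.

Emulates the statistical structure of carrier-assisted (high-background)
histone-mark ChIP-seq across the oocyte-to-embryo transition, plus the
matching expression and qPCR layers:

* a broad, promoter-enriched mark riding on a high uniform background;
* near-global erasure of the mark between the GV and MII oocyte stages,
  with re-establishment by the two-cell embryo stage;
* retention of the GV pattern in MII for a maternal-knockout genotype;
* an active mark (narrow, promoter-peaked) and a repressive mark (broad)
  with structured overlap, for co-occupancy analyses;
* an expression layer in which ZGA genes switch on between the zygote and
  two-cell stages, a subset of which is silenced in the knockout;
* a Ct table consistent with perfect template doubling plus Gaussian noise.

Every generator is a pure function of its parameters and seed.  Marked-gene
sets, ZGA genes and the knockout-sensitive subset are returned as
:class:`SimTruth` so downstream recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import (
    Chromosome,
    GeneRecord,
    GenomeAnnotation,
    GenomicInterval,
    DEFAULT_FLANK,
)

__all__ = [
    "StageMarkModel",
    "SimTruth",
    "SampleInfo",
    "ReadSet",
    "simulate_genome",
    "simulate_reads",
    "simulate_expression",
    "simulate_qpcr",
    "StudyDesign",
    "simulate_study",
    "read_bed_reads",
]

STAGES = ("GV", "MII", "zygote", "twocell")
GENOTYPES = ("WT", "cKO")
MARKS = ("H2AK119ub1", "H3K4me3", "H3K27me3")

READ_LENGTH = 50  # bp; mirrors trimming of sequenced reads to 50 bp


@dataclass(frozen=True)
class StageMarkModel:
    """Signal model for one (stage, genotype, mark) combination."""

    stage: str
    genotype: str
    mark: str
    occupancy: float          # fraction of genes carrying the mark
    enrichment: float = 20.0  # fold over background within the marked domain
    domain_width: int = 4000  # bp, centered on the TSS

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")
        if self.enrichment < 1.0:
            raise ValueError("enrichment must be >= 1")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")


@dataclass
class SimTruth:
    """Planted labels: which genes carry which mark where, and the ZGA sets."""

    marked_genes: dict[tuple[str, str, str], frozenset[str]] = field(default_factory=dict)
    zga_genes: frozenset[str] = frozenset()
    usp16_sensitive: frozenset[str] = frozenset()
    seed: int = 0

    def marked(self, stage: str, genotype: str = "WT", mark: str = "H2AK119ub1") -> frozenset[str]:
        return self.marked_genes.get((stage, genotype, mark), frozenset())

    def validate(self) -> None:
        if not self.usp16_sensitive <= self.zga_genes:
            raise ValueError("usp16_sensitive must be a subset of zga_genes")
        wt = self.marked("MII", "WT")
        cko = self.marked("MII", "cKO")
        if cko and not wt <= cko:
            raise ValueError("cKO MII marked set must contain the WT MII marked set")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "marked_genes": {
                "|".join(k): sorted(v) for k, v in self.marked_genes.items()
            },
            "zga_genes": sorted(self.zga_genes),
            "usp16_sensitive": sorted(self.usp16_sensitive),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            marked_genes={
                tuple(k.split("|")): frozenset(v)
                for k, v in payload["marked_genes"].items()
            },
            zga_genes=frozenset(payload["zga_genes"]),
            usp16_sensitive=frozenset(payload["usp16_sensitive"]),
            seed=payload["seed"],
        )


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    stage: str
    genotype: str
    mark: str
    replicate: int


@dataclass
class ReadSet:
    """Aligned, fixed-length single-end reads for one sample."""

    sample: SampleInfo
    reads: pd.DataFrame  # columns: chrom, start, end, strand

    @property
    def total(self) -> int:
        return len(self.reads)

    def write_bed(self, path: str | Path) -> None:
        df = self.reads
        with open(path, "w") as fh:
            for i, (chrom, start, end, strand) in enumerate(
                zip(df["chrom"], df["start"], df["end"], df["strand"])
            ):
                fh.write(f"{chrom}\t{start}\t{end}\tr{i}\t0\t{strand}\n")


def read_bed_reads(path: str | Path, sample: SampleInfo) -> ReadSet:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        p = line.split("\t")
        rows.append((p[0], int(p[1]), int(p[2]), p[5] if len(p) > 5 else "+"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return ReadSet(sample, df)


# -- genome ----------------------------------------------------------------


def simulate_genome(
    n_chrom: int = 3,
    chrom_length: int = 5_000_000,
    n_genes: int = 300,
    gene_length: int = 4000,
    flank: int = DEFAULT_FLANK,
    seed: int | np.random.Generator = 0,
) -> GenomeAnnotation:
    """Place non-overlapping genes whose promoters also do not overlap.

    Genes are dropped into randomly chosen slots of width
    ``2*flank + gene_length`` on a regular raster, with random strands, so
    promoter windows never collide.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    slot = 2 * flank + gene_length
    slots_per_chrom = chrom_length // slot
    total_slots = n_chrom * slots_per_chrom
    if n_genes > total_slots:
        raise ValueError(
            f"cannot place {n_genes} genes: only {total_slots} slots of {slot} bp"
        )
    chroms = [Chromosome(f"chr{i + 1}", chrom_length) for i in range(n_chrom)]
    picked = np.sort(rng.choice(total_slots, size=n_genes, replace=False))
    strands = rng.choice(["+", "-"], size=n_genes)
    ann = GenomeAnnotation(chroms)
    for i, (s, strand) in enumerate(zip(picked, strands)):
        c, k = divmod(int(s), slots_per_chrom)
        start = k * slot + flank
        ann.add_gene(
            GeneRecord(f"g{i + 1:04d}", chroms[c].name, str(strand), start, start + gene_length)
        )
    return ann


# -- ChIP reads ------------------------------------------------------------


def simulate_reads(
    ann: GenomeAnnotation,
    model: StageMarkModel,
    marked_genes: Sequence[str] | frozenset[str],
    depth: int = 500_000,
    background_fraction: float = 0.7,
    duplicate_rate: float = 0.1,
    read_length: int = READ_LENGTH,
    enrichment_per_gene: Mapping[str, float] | None = None,
    seed: int | np.random.Generator = 0,
    sample_id: str | None = None,
    replicate: int = 1,
) -> ReadSet:
    """Draw one sample's reads: uniform background plus promoter-domain signal.

    ``background_fraction * depth`` reads fall uniformly over the genome
    (the carrier-ChIP background); the remainder is spread over the marked
    genes' TSS-centered domains proportionally to per-gene enrichment
    (equal by default), with a triangular within-domain density peaked at
    the TSS.  PCR duplicates are injected as exact coordinate copies at
    ``duplicate_rate`` and the stated ``depth`` counts unique reads before
    duplication.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not 0.0 <= background_fraction <= 1.0:
        raise ValueError("background_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    marked = [g for g in ann.gene_ids if g in set(marked_genes)]
    n_bg = int(round(background_fraction * depth))
    n_sig = depth - n_bg if marked else 0
    n_bg = depth - n_sig

    chroms = list(ann.chromosomes)
    lengths = np.array([ann.chromosomes[c] for c in chroms], dtype=np.float64)
    chrom_codes = []
    starts = []

    if n_bg > 0:
        which = rng.choice(len(chroms), size=n_bg, p=lengths / lengths.sum())
        hi = (lengths - read_length)[which]
        pos = (rng.random(n_bg) * hi).astype(np.int64)
        chrom_codes.append(which)
        starts.append(pos)

    if n_sig > 0:
        weights = np.array(
            [
                (enrichment_per_gene or {}).get(g, model.enrichment)
                for g in marked
            ],
            dtype=np.float64,
        )
        weights /= weights.sum()
        gene_idx = rng.choice(len(marked), size=n_sig, p=weights)
        half = model.domain_width // 2
        g_chrom = np.empty(n_sig, dtype=np.int64)
        g_start = np.empty(n_sig, dtype=np.int64)
        chrom_of = {c: i for i, c in enumerate(chroms)}
        tss = np.array([ann.genes[g].tss for g in marked], dtype=np.int64)
        gchrom = np.array([chrom_of[ann.genes[g].chrom] for g in marked], dtype=np.int64)
        # triangular density peaked at the TSS and vanishing at the domain
        # edges, so the expected signal profile has a unique maximum at 0;
        # reads are placed by their midpoints
        offs = ((rng.random(n_sig) + rng.random(n_sig) - 1.0) * half).astype(np.int64)
        g_chrom = gchrom[gene_idx]
        g_start = tss[gene_idx] + offs - read_length // 2
        # keep reads within chromosome bounds
        clens = np.array([ann.chromosomes[c] for c in chroms], dtype=np.int64)
        g_start = np.clip(g_start, 0, clens[g_chrom] - read_length)
        chrom_codes.append(g_chrom)
        starts.append(g_start)

    codes = np.concatenate(chrom_codes) if chrom_codes else np.empty(0, dtype=np.int64)
    pos = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
    strand = rng.choice(["+", "-"], size=len(pos))

    if duplicate_rate > 0 and len(pos):
        dup_mask = rng.random(len(pos)) < duplicate_rate
        codes = np.concatenate([codes, codes[dup_mask]])
        pos = np.concatenate([pos, pos[dup_mask]])
        strand = np.concatenate([strand, strand[dup_mask]])

    order = rng.permutation(len(pos))
    df = pd.DataFrame(
        {
            "chrom": np.array(chroms, dtype=object)[codes[order]],
            "start": pos[order],
            "end": pos[order] + read_length,
            "strand": strand[order],
        }
    )
    sid = sample_id or f"{model.mark}_{model.stage}_{model.genotype}_rep{replicate}"
    info = SampleInfo(sid, model.stage, model.genotype, model.mark, replicate)
    return ReadSet(info, df)


# -- expression ------------------------------------------------------------


def simulate_expression(
    ann: GenomeAnnotation,
    truth: SimTruth,
    stages: Sequence[tuple[str, str]] = (
        ("zygote", "WT"),
        ("zygote", "cKO"),
        ("twocell", "WT"),
        ("twocell", "cKO"),
    ),
    n_replicates: int = 2,
    noise_sd: float = 0.0,
    baseline_fpkm: float = 5.0,
    zga_pre_fpkm: float = 0.4,
    zga_fold: float = 10.0,
    sensitive_fold: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """FPKM table (genes x samples) with the ZGA switch planted.

    ZGA genes sit below 1 FPKM in zygotes and rise ``zga_fold`` times the
    floored zygote value at the two-cell stage in WT; knockout-sensitive
    ZGA genes stay ``sensitive_fold`` below WT in cKO two-cell embryos.
    Noise is multiplicative log-normal: fpkm * exp(N(0, noise_sd)).
    Columns are named ``{stage}_{genotype}_r{rep}``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = ann.gene_ids
    zga = truth.zga_genes
    sens = truth.usp16_sensitive
    if not zga <= set(genes):
        raise ValueError("zga_genes must be a subset of the annotation's genes")
    cols = {}
    for stage, genotype in stages:
        base = np.full(len(genes), baseline_fpkm)
        for i, g in enumerate(genes):
            if g in zga:
                if stage in ("GV", "MII", "zygote"):
                    base[i] = zga_pre_fpkm
                else:  # two-cell: activated
                    level = max(zga_pre_fpkm, 1.0) * zga_fold
                    if genotype == "cKO" and g in sens:
                        level /= sensitive_fold
                    base[i] = level
        for rep in range(1, n_replicates + 1):
            noisy = base * np.exp(rng.normal(0.0, noise_sd, size=len(genes))) if noise_sd > 0 else base.copy()
            cols[f"{stage}_{genotype}_r{rep}"] = noisy
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))


# -- qPCR ------------------------------------------------------------------


def simulate_qpcr(
    true_ratio: float,
    efficiencies: tuple[float, float] = (1.0, 1.0),
    ct_gapdh: float = 18.0,
    ct_g2: float = 24.0,
    ct_plasmid_ref: float = 20.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int | np.random.Generator = 0,
) -> "pd.DataFrame":
    """Generate a Ct table whose inverse under the ratio formulas is `true_ratio`.

    The model is perfect template doubling (one Ct per 2x template).  The
    plasmid-standard Cts encode the primer-efficiency ratio e1/e2 and the
    sample Cts encode relative abundance true_ratio * e1/e2, so the
    absolute ratio (relative / efficiency) recovers `true_ratio` exactly at
    zero noise.  Rows are replicates; columns ct1..ct4, ct_g1, ct_g2, ct_ref.
    """
    if true_ratio <= 0:
        raise ValueError("true_ratio must be > 0")
    e1, e2 = efficiencies
    if e1 <= 0 or e2 <= 0:
        raise ValueError("efficiencies must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ct1 = ct_plasmid_ref - np.log2(e1)
    ct2 = ct_plasmid_ref - np.log2(e2)
    ct3 = ct4 = ct_plasmid_ref
    ct_g1 = ct_g2 - np.log2(true_ratio * e1 / e2)
    base = {
        "ct1": ct1, "ct2": ct2, "ct3": ct3, "ct4": ct4,
        "ct_g1": ct_g1, "ct_g2": ct_g2, "ct_ref": ct_gapdh,
    }
    rows = []
    for _ in range(n_replicates):
        rows.append(
            {k: v + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0) for k, v in base.items()}
        )
    return pd.DataFrame(rows)


# -- full study design -----------------------------------------------------


@dataclass
class StudyDesign:
    """Default study conditions for the planted synthetic experiment.

    300 genes on 3 x 5 Mb chromosomes; 150 carry the repressive ub mark at
    the GV stage, 90% of which lose it at MII in WT while the knockout
    retains the full GV pattern; the two-cell embryo re-establishes most of
    the GV pattern except at a small subset (the planted two-cell losses,
    drawn from the MII losses).  Depth 5e5 unique reads per ChIP sample,
    70% uniform background, 3 replicates.
    """

    n_chrom: int = 3
    chrom_length: int = 5_000_000
    n_genes: int = 300
    n_gv_marked: int = 150
    mii_loss_fraction: float = 0.9
    n_twocell_down: int = 30
    n_zga: int = 60
    n_usp16_sensitive: int = 20
    depth: int = 500_000
    background_fraction: float = 0.7
    enrichment: float = 20.0
    domain_width: int = 4000
    duplicate_rate: float = 0.1
    n_replicates: int = 3
    expression_noise_sd: float = 0.0
    n_k4_marked: int = 180
    n_k27_marked: int = 90

    def validate(self) -> list[str]:
        problems = []
        if self.n_gv_marked > self.n_genes:
            problems.append("n_gv_marked exceeds n_genes")
        if self.n_zga > self.n_genes:
            problems.append("n_zga exceeds n_genes")
        if self.n_usp16_sensitive > self.n_zga:
            problems.append("n_usp16_sensitive exceeds n_zga")
        if not 0 <= self.mii_loss_fraction <= 1:
            problems.append("mii_loss_fraction outside [0, 1]")
        if self.n_twocell_down > int(round(self.n_gv_marked * self.mii_loss_fraction)):
            problems.append("n_twocell_down exceeds the number of MII losses")
        return problems


def _plant_truth(ann: GenomeAnnotation, design: StudyDesign, rng: np.random.Generator, seed: int) -> SimTruth:
    genes = np.array(ann.gene_ids)
    gv_marked = rng.choice(genes, size=design.n_gv_marked, replace=False)
    n_keep = design.n_gv_marked - int(round(design.n_gv_marked * design.mii_loss_fraction))
    mii_marked = rng.choice(gv_marked, size=n_keep, replace=False)
    losses = np.array(sorted(set(gv_marked) - set(mii_marked)))
    twocell_down = rng.choice(losses, size=design.n_twocell_down, replace=False)
    twocell_marked = sorted(set(gv_marked) - set(twocell_down))
    # ZGA genes drawn preferentially outside the GV-marked set is NOT imposed:
    # uniform draw keeps the expression and chromatin layers independent.
    zga = rng.choice(genes, size=design.n_zga, replace=False)
    sens = rng.choice(zga, size=design.n_usp16_sensitive, replace=False)
    # co-occupancy layer: the active mark prefers non-ub genes, the
    # repressive K27 mark is drawn from within the ub-marked set.
    k4 = rng.choice(genes, size=design.n_k4_marked, replace=False)
    k27 = rng.choice(gv_marked, size=min(design.n_k27_marked, len(gv_marked)), replace=False)
    ub = "H2AK119ub1"
    marked = {
        ("GV", "WT", ub): frozenset(gv_marked),
        ("GV", "cKO", ub): frozenset(gv_marked),
        ("MII", "WT", ub): frozenset(mii_marked),
        ("MII", "cKO", ub): frozenset(gv_marked),
        ("twocell", "WT", ub): frozenset(twocell_marked),
        ("zygote", "WT", ub): frozenset(twocell_marked),
        ("GV", "WT", "H3K4me3"): frozenset(k4),
        ("GV", "WT", "H3K27me3"): frozenset(k27),
    }
    truth = SimTruth(marked_genes=marked, zga_genes=frozenset(zga),
                     usp16_sensitive=frozenset(sens), seed=seed)
    truth.validate()
    return truth


def simulate_study(
    design: StudyDesign | None = None, seed: int = 0
) -> tuple[GenomeAnnotation, SimTruth, dict[str, ReadSet], pd.DataFrame]:
    """Generate the full default experiment: genome, truth, reads, expression.

    Returns (annotation, truth, readsets, fpkm table) where readsets maps
    sample_id -> ReadSet for the ub mark at GV/MII/twocell in WT and MII in
    cKO (``n_replicates`` each), plus single-replicate GV tracks of the
    active (H3K4me3) and repressive (H3K27me3) marks for co-occupancy.
    """
    design = design or StudyDesign()
    problems = design.validate()
    if problems:
        raise ValueError("invalid study design: " + "; ".join(problems))
    root = np.random.SeedSequence(seed)
    ss = root.spawn(4)
    rng_genome = np.random.default_rng(ss[0])
    rng_truth = np.random.default_rng(ss[1])
    ann = simulate_genome(
        design.n_chrom, design.chrom_length, design.n_genes, seed=rng_genome
    )
    truth = _plant_truth(ann, design, rng_truth, seed)

    ub = "H2AK119ub1"
    conditions = [
        ("GV", "WT", ub, design.n_replicates),
        ("MII", "WT", ub, design.n_replicates),
        ("MII", "cKO", ub, design.n_replicates),
        ("twocell", "WT", ub, design.n_replicates),
        ("GV", "WT", "H3K4me3", 1),
        ("GV", "WT", "H3K27me3", 1),
    ]
    readsets: dict[str, ReadSet] = {}
    read_seeds = ss[2].spawn(sum(n for *_, n in conditions))
    i = 0
    for stage, genotype, mark, n_rep in conditions:
        marked = truth.marked(stage, genotype, mark)
        occupancy = len(marked) / len(ann)
        domain_width = design.domain_width if mark != "H3K4me3" else design.domain_width // 2
        model = StageMarkModel(stage, genotype, mark, occupancy,
                               design.enrichment, domain_width)
        for rep in range(1, n_rep + 1):
            rs = simulate_reads(
                ann, model, marked,
                depth=design.depth,
                background_fraction=design.background_fraction,
                duplicate_rate=design.duplicate_rate,
                seed=np.random.default_rng(read_seeds[i]),
                replicate=rep,
            )
            readsets[rs.sample.sample_id] = rs
            i += 1

    fpkm = simulate_expression(
        ann, truth,
        n_replicates=2,
        noise_sd=design.expression_noise_sd,
        seed=np.random.default_rng(ss[3]),
    )
    return ann, truth, readsets, fpkm
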