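"""Promoter-level quantification and stage-wise differential enrichment.

Counts are reads whose midpoints fall inside each TSS +/- 2 kb promoter.
The differential test is a negative-binomial Wald test on the log2 fold
change of normalized group means: per-gene dispersion is estimated by
method of moments pooled across the two groups (floored at 1e-8), the
variance of each group's mean follows the NB mean-variance relation, and
p-values use a t reference with the pooled residual degrees of freedom to
account for the dispersion being estimated from few replicates.
Benjamini-Hochberg adjustment is applied across tested genes.

Normalization factors can come either from the median-of-ratios estimator
(appropriate when most promoters are unchanged) or, for contrasts with
near-global signal loss, from each sample's background level in random
regions — the same anchor the track normalization uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_model import GenomicInterval, PromoterRegion
from .synthetic_data import ReadSet, SampleInfo
from .expression import GeneSetCatalog

__all__ = [
    "PromoterSignalMatrix",
    "promoter_counts",
    "size_factors",
    "background_norm_factors",
    "nb_wald_test",
    "call_changes",
    "derive_ub_gene_sets",
]

DISPERSION_FLOOR = 1e-8
DEFAULT_MIN_SIGNAL = 5.0
DEFAULT_Q_MAX = 0.05
DEFAULT_MIN_ABS_LFC = 1.0


@dataclass
class PromoterSignalMatrix:
    """Genes x samples promoter read counts with sample metadata."""

    counts: pd.DataFrame                      # index gene_id, columns sample_id
    samples: dict[str, SampleInfo]
    promoter_widths: pd.Series                # per gene, bp
    norm_factors: pd.Series | None = None     # per sample; geometric mean 1

    def rpkm(self) -> pd.DataFrame:
        depth = self.counts.sum(axis=0)
        kb = self.promoter_widths / 1000.0
        return self.counts.div(depth / 1e6, axis=1).div(kb, axis=0)


def promoter_counts(
    readsets: Mapping[str, ReadSet] | Sequence[ReadSet],
    promoters: Mapping[str, PromoterRegion],
) -> PromoterSignalMatrix:
    """Count deduplicated reads whose midpoints fall in each promoter."""
    if not isinstance(readsets, Mapping):
        readsets = {rs.sample.sample_id: rs for rs in readsets}
    gene_ids = list(promoters)
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for gi, gid in enumerate(gene_ids):
        iv = promoters[gid].interval
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, gi))
    chrom_arrays = {}
    for chrom, triples in by_chrom.items():
        triples.sort()
        starts = np.array([t[0] for t in triples], dtype=np.int64)
        ends = np.array([t[1] for t in triples], dtype=np.int64)
        idx = np.array([t[2] for t in triples], dtype=np.int64)
        chrom_arrays[chrom] = (starts, ends, idx)

    data = {}
    for sid, rs in readsets.items():
        counts = np.zeros(len(gene_ids), dtype=np.int64)
        for chrom, g in rs.reads.groupby("chrom", observed=True):
            arr = chrom_arrays.get(chrom)
            if arr is None:
                continue
            starts, ends, idx = arr
            mids = ((g["start"].to_numpy() + g["end"].to_numpy()) // 2).astype(np.int64)
            j = np.searchsorted(starts, mids, side="right") - 1
            ok = j >= 0
            ok[ok] &= mids[ok] < ends[j[ok]]
            np.add.at(counts, idx[j[ok]], 1)
        data[sid] = counts
    counts_df = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    widths = pd.Series(
        {gid: promoters[gid].interval.width for gid in gene_ids}, name="width"
    )
    samples = {sid: rs.sample for sid, rs in readsets.items()}
    return PromoterSignalMatrix(counts_df, samples, widths)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with all-positive counts."""
    pos = counts[(counts > 0).all(axis=1)]
    if pos.empty:
        raise ValueError(
            "no gene has positive counts in every sample; consider adding a pseudo-count"
        )
    log_geo = np.log(pos).mean(axis=1)
    ratios = np.log(pos).sub(log_geo, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def background_norm_factors(
    matrix: PromoterSignalMatrix, background_counts: Mapping[str, float]
) -> pd.Series:
    """Normalization factors proportional to per-sample background levels.

    `background_counts` is e.g. the mean raw tile count over random-region
    tiles per sample; factors are rescaled to geometric mean 1.
    """
    f = pd.Series({s: float(background_counts[s]) for s in matrix.counts.columns})
    if (f <= 0).any():
        raise ValueError("background counts must be positive")
    return (f / np.exp(np.log(f).mean())).rename("size_factor")


def _group_stats(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return y.mean(axis=1), y.var(axis=1, ddof=1)


def nb_wald_test(
    matrix: PromoterSignalMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    norm_factors: pd.Series | None = None,
    min_signal: float = DEFAULT_MIN_SIGNAL,
) -> pd.DataFrame:
    """NB Wald test of group B over group A on normalized promoter counts.

    Returns a DataFrame indexed by gene with columns base_mean, log2_fc,
    stat, p_value, q_value.  Genes whose normalized counts are below
    ``min_signal`` in every sample are not tested (rows dropped).
    """
    for grp, name in ((group_a, "A"), (group_b, "B")):
        if len(grp) < 2:
            raise ValueError(f"group {name} needs >= 2 replicates, got {len(grp)}")
        missing = set(grp) - set(matrix.counts.columns)
        if missing:
            raise ValueError(f"unknown samples in group {name}: {sorted(missing)}")
    if norm_factors is None:
        norm_factors = (
            matrix.norm_factors
            if matrix.norm_factors is not None
            else size_factors(matrix.counts[list(group_a) + list(group_b)])
        )
    cols = list(group_a) + list(group_b)
    y = matrix.counts[cols].to_numpy(dtype=np.float64) / norm_factors[cols].to_numpy()
    keep = (y >= min_signal).any(axis=1)
    y = y[keep]
    genes = matrix.counts.index[keep]
    na, nb = len(group_a), len(group_b)
    ya, yb = y[:, :na], y[:, na:]
    ma, va = _group_stats(ya)
    mb, vb = _group_stats(yb)

    df_resid = na + nb - 2
    # pooled method-of-moments dispersion: alpha = (var - mean) / mean^2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_a = (va - ma) / np.square(ma)
        alpha_b = (vb - mb) / np.square(mb)
    alpha = ((na - 1) * np.nan_to_num(alpha_a) + (nb - 1) * np.nan_to_num(alpha_b)) / df_resid
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    eps = 0.5  # symmetric pseudo-mean keeps label-swap antisymmetry exact
    mu_a, mu_b = ma + eps, mb + eps
    lfc = np.log2(mu_b / mu_a)
    ln2sq = np.log(2.0) ** 2
    var_log_a = (mu_a + alpha * mu_a**2) / (na * mu_a**2 * ln2sq)
    var_log_b = (mu_b + alpha * mu_b**2) / (nb * mu_b**2 * ln2sq)
    se = np.sqrt(var_log_a + var_log_b)
    stat = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(stat), df_resid)
    p = np.clip(p, 0.0, 1.0)
    q = multipletests(p, method="fdr_bh")[1] if len(p) else p
    return pd.DataFrame(
        {
            "base_mean": (ma * na + mb * nb) / (na + nb),
            "log2_fc": lfc,
            "stat": stat,
            "p_value": p,
            "q_value": q,
        },
        index=genes,
    )


def call_changes(
    result: pd.DataFrame,
    q_max: float = DEFAULT_Q_MAX,
    min_abs_lfc: float = DEFAULT_MIN_ABS_LFC,
) -> pd.Series:
    """Classify each tested gene as up / down / unchanged (B over A)."""
    call = pd.Series("unchanged", index=result.index, name="call")
    sig = result["q_value"] < q_max
    call[sig & (result["log2_fc"] > min_abs_lfc)] = "up"
    call[sig & (result["log2_fc"] < -min_abs_lfc)] = "down"
    return call


def derive_ub_gene_sets(
    contrasts: Mapping[str, pd.DataFrame],
    q_max: float = DEFAULT_Q_MAX,
    min_abs_lfc: float = DEFAULT_MIN_ABS_LFC,
) -> tuple[GeneSetCatalog, dict[str, int]]:
    """Build the stage-wise promoter-mark gene sets from three contrasts.

    Expects contrasts keyed 'GV_vs_MII', 'GV_vs_twocell' (both WT; B = the
    later stage) and 'WTMII_vs_cKOMII' (B = cKO).  Produces:

    * MII-ub-down      — promoter mark significantly down GV -> MII;
    * two-cell-ub-down — promoter mark significantly down GV -> two-cell;
    * cKO-MII-ub-up    — promoter mark significantly up in knockout MII.

    Returns the catalog plus Venn counts of the MII-down / cKO-up overlap.
    """
    required = ("GV_vs_MII", "GV_vs_twocell", "WTMII_vs_cKOMII")
    for key in required:
        if key not in contrasts:
            raise ValueError(f"missing contrast {key!r}")
    catalog = GeneSetCatalog()

    def _select(key: str, direction: str) -> frozenset[str]:
        res = contrasts[key]
        call = call_changes(res, q_max, min_abs_lfc)
        return frozenset(res.index[call == direction])

    mii_down = _select("GV_vs_MII", "down")
    twocell_down = _select("GV_vs_twocell", "down")
    cko_up = _select("WTMII_vs_cKOMII", "up")
    prov = {"q_max": q_max, "min_abs_lfc": min_abs_lfc}
    catalog.add("MII-ub-down", mii_down, {**prov, "contrast": "GV_vs_MII"})
    catalog.add("two-cell-ub-down", twocell_down, {**prov, "contrast": "GV_vs_twocell"})
    catalog.add("cKO-MII-ub-up", cko_up, {**prov, "contrast": "WTMII_vs_cKOMII"})
    venn = {
        "MII-ub-down": len(mii_down),
        "cKO-MII-ub-up": len(cko_up),
        "two-cell-ub-down": len(twocell_down),
        "cKO-up&MII-down": len(cko_up & mii_down),
        "twocell-down&MII-down": len(twocell_down & mii_down),
    }
    return catalog, venn
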