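"""FPKM table hygiene and expression-side gene-set logic.

The flooring rule removes genes below 1 FPKM in every sample and clamps the
remaining sub-1 values up to 1 before any fold change is computed, so that
small absolute changes at barely-expressed genes cannot produce dramatic
ratios.  Zygotic genome activation (ZGA) genes are those whose floored
two-cell / zygote fold change exceeds 3; knockout-responsive transcripts
use the same 3-fold rule in either direction; and ZGA genes are partitioned
into knockout-sensitive and -insensitive classes by intersection with the
down-regulated list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ExpressionTable",
    "GeneSetCatalog",
    "floor_fpkm",
    "define_zga",
    "differential_transcripts",
    "overlap_with_zga",
    "classify_zga_sensitivity",
]

DEFAULT_FC = 3.0


class GeneSetCatalog:
    """Named gene sets with provenance (contrast, thresholds, seeds...)."""

    def __init__(self) -> None:
        self._sets: dict[str, frozenset[str]] = {}
        self._provenance: dict[str, dict] = {}

    def add(self, name: str, genes: Iterable[str], provenance: dict | None = None) -> None:
        if name in self._sets:
            raise ValueError(f"gene set {name!r} already defined")
        self._sets[name] = frozenset(genes)
        self._provenance[name] = dict(provenance or {})

    def __getitem__(self, name: str) -> frozenset[str]:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def provenance(self, name: str) -> dict:
        return self._provenance[name]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, genes in self._sets.items():
            fname = name.replace("/", "_") + ".txt"
            (outdir / fname).write_text("".join(f"{g}\n" for g in sorted(genes)))
        (outdir / "provenance.json").write_text(json.dumps(self._provenance, indent=1, default=str))


@dataclass
class ExpressionTable:
    """FPKM values (genes x samples) plus a sample -> condition mapping."""

    fpkm: pd.DataFrame
    conditions: dict[str, str]
    floored: bool = False

    def __post_init__(self) -> None:
        missing = set(self.fpkm.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without a condition label: {sorted(missing)}")
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @classmethod
    def from_wide(cls, fpkm: pd.DataFrame) -> "ExpressionTable":
        """Columns named '{condition}_r{n}' (or plain condition names)."""
        conditions = {}
        for col in fpkm.columns:
            base, _, rep = col.rpartition("_r")
            conditions[col] = base if rep.isdigit() and base else col
        return cls(fpkm, conditions)

    def condition_values(self, condition: str, agg: str = "mean") -> pd.Series:
        cols = [s for s, c in self.conditions.items() if c == condition]
        if not cols:
            raise ValueError(f"no samples for condition {condition!r}")
        block = self.fpkm[cols]
        return block.mean(axis=1) if agg == "mean" else block.median(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        self.fpkm.to_csv(path, sep="\t", float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path, floored: bool = False) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        t = cls.from_wide(df)
        t.floored = floored
        return t


def floor_fpkm(table: ExpressionTable) -> ExpressionTable:
    """Drop genes with FPKM < 1 in all samples, clamp remaining values to >= 1."""
    if table.floored:
        raise ValueError("table is already floored")
    keep = (table.fpkm >= 1.0).any(axis=1)
    floored = table.fpkm[keep].clip(lower=1.0)
    return ExpressionTable(floored, dict(table.conditions), floored=True)


def _require_floored(table: ExpressionTable) -> None:
    if not table.floored:
        raise ValueError("fold changes require a floored table; call floor_fpkm first")


def define_zga(
    table: ExpressionTable,
    zygote_condition: str = "zygote_WT",
    twocell_condition: str = "twocell_WT",
    fc_threshold: float = DEFAULT_FC,
) -> frozenset[str]:
    """ZGA genes: floored two-cell / zygote fold change strictly above threshold."""
    _require_floored(table)
    zy = table.condition_values(zygote_condition)
    tc = table.condition_values(twocell_condition)
    fc = tc / zy
    return frozenset(fc.index[fc > fc_threshold])


def differential_transcripts(
    table: ExpressionTable,
    wt_condition: str,
    cko_condition: str,
    fc_threshold: float = DEFAULT_FC,
) -> tuple[frozenset[str], frozenset[str]]:
    """(up, down) transcript sets for knockout over wild type at one stage.

    up: cKO/WT > threshold; down: WT/cKO > threshold.  Disjoint by
    construction for threshold >= 1.
    """
    _require_floored(table)
    wt = table.condition_values(wt_condition)
    ko = table.condition_values(cko_condition)
    up = frozenset(wt.index[(ko / wt) > fc_threshold])
    down = frozenset(wt.index[(wt / ko) > fc_threshold])
    return up, down


def overlap_with_zga(
    down: frozenset[str], zga: frozenset[str]
) -> tuple[frozenset[str], float, dict[str, int]]:
    """Intersection of down-regulated transcripts with ZGA genes.

    Returns (overlap set, fraction of `down` that is ZGA, Venn counts).
    """
    inter = down & zga
    fraction = len(inter) / len(down) if down else 0.0
    venn = {
        "down_only": len(down - zga),
        "zga_only": len(zga - down),
        "both": len(inter),
    }
    return frozenset(inter), fraction, venn


def classify_zga_sensitivity(
    zga: frozenset[str], cko_down: frozenset[str]
) -> tuple[frozenset[str], frozenset[str]]:
    """Partition ZGA genes into knockout-sensitive and -insensitive classes."""
    sensitive = zga & cko_down
    return frozenset(sensitive), frozenset(zga - sensitive)
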