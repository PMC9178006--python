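"""Relative and absolute RT-qPCR ratio computations.

The amplification base is fixed at 2 (one cycle threshold per template
doubling).  Primer efficiencies of the two gene assays are compared on
plasmid standards that pair each gene's primers with a reference (Gfp)
primer set on the same plasmid:

    efficiency = 2^-(Ct1 - Ct3) / 2^-(Ct2 - Ct4)

The relative transcript ratio normalizes both genes' sample Cts to a
housekeeping reference (Gapdh), which cancels algebraically:

    relative = 2^-(Ct_g1 - Ct_ref) / 2^-(Ct_g2 - Ct_ref) = 2^(Ct_g2 - Ct_g1)

and the absolute ratio is the relative ratio divided by the primer
efficiency.  Replicate Cts are averaged on the Ct scale (equivalent to a
geometric mean on the quantity scale) before exponentiation.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "primer_efficiency_ratio",
    "relative_ratio",
    "absolute_ratio",
    "ratios_from_ct_table",
]

_FIELDS = ("ct1", "ct2", "ct3", "ct4", "ct_g1", "ct_g2", "ct_ref")


def _check_finite(**cts: float) -> None:
    for name, v in cts.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


def primer_efficiency_ratio(ct1: float, ct2: float, ct3: float, ct4: float) -> float:
    """Efficiency ratio of the two gene assays from plasmid-standard Cts."""
    _check_finite(ct1=ct1, ct2=ct2, ct3=ct3, ct4=ct4)
    return 2.0 ** -(ct1 - ct3) / 2.0 ** -(ct2 - ct4)


def relative_ratio(ct_g1: float, ct_g2: float, ct_ref: float) -> float:
    """Reference-normalized transcript ratio; the reference Ct cancels."""
    _check_finite(ct_g1=ct_g1, ct_g2=ct_g2, ct_ref=ct_ref)
    return 2.0 ** -(ct_g1 - ct_ref) / 2.0 ** -(ct_g2 - ct_ref)


def absolute_ratio(relative: float, efficiency: float) -> float:
    """Absolute transcript ratio: relative ratio corrected for primer efficiency."""
    if efficiency <= 0:
        raise ValueError("efficiency must be > 0")
    return relative / efficiency


def ratios_from_ct_table(table: pd.DataFrame) -> pd.Series:
    """Efficiency, relative and absolute ratios from a replicate Ct table.

    `table` has one row per replicate and columns ct1..ct4, ct_g1, ct_g2,
    ct_ref.  Replicates are averaged on the Ct scale; the returned Series
    also carries the replicate SEM of the absolute ratio obtained by
    applying the formulas per replicate.
    """
    missing = [c for c in _FIELDS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    m = table[list(_FIELDS)].mean()
    eff = primer_efficiency_ratio(m["ct1"], m["ct2"], m["ct3"], m["ct4"])
    rel = relative_ratio(m["ct_g1"], m["ct_g2"], m["ct_ref"])
    absr = absolute_ratio(rel, eff)
    per_rep = [
        absolute_ratio(
            relative_ratio(r.ct_g1, r.ct_g2, r.ct_ref),
            primer_efficiency_ratio(r.ct1, r.ct2, r.ct3, r.ct4),
        )
        for r in table.itertuples()
    ]
    sem = float(np.std(per_rep, ddof=1) / np.sqrt(len(per_rep))) if len(per_rep) > 1 else 0.0
    return pd.Series(
        {"efficiency": eff, "relative": rel, "absolute": absr, "absolute_sem": sem}
    )
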