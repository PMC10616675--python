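"""Differential-expression thresholding and cross-tabulation.

The differential-expression engine itself is consumed, not reimplemented:
this module applies fold-change / adjusted-p / expression-floor gates to an
externally produced result table (one row per gene with ``log2fc``,
``padj`` and ``control_mean``) and computes the set overlaps and
known-target flags reported alongside.  The fold-change gate is two-sided
on magnitude, with the sign assigning genes to the up- or down-regulated
set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEGThresholds",
    "log2fc_of_fold",
    "apply_deg_thresholds",
    "overlap_sets",
    "flag_known_targets",
]

logger = logging.getLogger(__name__)


def log2fc_of_fold(raw_fold: float) -> float:
    """Base-2 log of a raw fold change (1.3-fold -> 0.3785)."""
    if raw_fold <= 0:
        raise ValueError(f"raw fold change must be positive, got {raw_fold}")
    return math.log2(raw_fold)


@dataclass(frozen=True)
class DEGThresholds:
    """Gates for calling differential expression from a result table.

    ``min_abs_log2fc`` defaults to log2(1.3) = 0.3785 (a 1.3-fold change);
    ``excluded_genes`` removes the knocked-out gene(s) and the artefactually
    elevated Plekhg2 from consideration.
    """

    min_abs_log2fc: float = 0.3785
    max_padj: float = 0.05
    min_control_fpkm: float = 0.1
    excluded_genes: tuple[str, ...] = ("Zfp36", "Plekhg2")

    def __post_init__(self) -> None:
        if self.min_abs_log2fc <= 0 or self.max_padj <= 0:
            raise ValueError("thresholds must be positive")


def apply_deg_thresholds(
    table: pd.DataFrame, thresholds: DEGThresholds = DEGThresholds()
) -> tuple[set[str], set[str], pd.DataFrame]:
    """Partition a DEG table into up / down sets with an exclusion report.

    up   = log2fc >= +t and padj <= max_padj and control_mean > floor and not excluded
    down = log2fc <= -t, same side conditions.
    The report lists, per gene, the reasons it failed to enter either set.
    """
    for col in ("log2fc", "padj", "control_mean"):
        if col not in table.columns:
            raise ValueError(f"DEG table missing required column {col!r}")
    t = thresholds
    excluded = {str(g) for g in t.excluded_genes}

    up: set[str] = set()
    down: set[str] = set()
    reasons_col = []
    for gene, row in table.iterrows():
        reasons = []
        if str(gene) in excluded or str(row.get("symbol", "")) in excluded:
            reasons.append("excluded_gene")
        if not (abs(row["log2fc"]) >= t.min_abs_log2fc) or np.isnan(row["log2fc"]):
            reasons.append("fold_change")
        if not (row["padj"] <= t.max_padj) or np.isnan(row["padj"]):
            reasons.append("padj")
        if not (row["control_mean"] > t.min_control_fpkm) or np.isnan(row["control_mean"]):
            reasons.append("low_expression")
        reasons_col.append(";".join(reasons))
        if not reasons:
            (up if row["log2fc"] > 0 else down).add(str(gene))
    report = pd.DataFrame({"reasons": reasons_col}, index=table.index)
    return up, down, report


def overlap_sets(set_a: Iterable[str], set_b: Iterable[str]) -> dict:
    """Venn partition of two gene sets: counts and memberships."""
    a, b = set(set_a), set(set_b)
    both = a & b
    return {
        "a_only": len(a - b),
        "b_only": len(b - a),
        "both": len(both),
        "members_a_only": sorted(a - b),
        "members_b_only": sorted(b - a),
        "members_both": sorted(both),
    }


def flag_known_targets(genes: Iterable[str], known_targets: Iterable[str]) -> tuple[pd.Series, float]:
    """Flag previously identified targets within a gene set, case-insensitively.

    Returns a per-gene boolean series plus the flagged fraction.  The
    known list is user-supplied; no curated biology ships with the package.
    """
    genes = list(genes)
    known = {str(k).lower() for k in known_targets}
    if not known:
        logger.warning("flag_known_targets: empty known-target list; all flags false")
    flags = pd.Series({g: str(g).lower() in known for g in genes}, dtype=bool)
    fraction = float(flags.mean()) if genes else 0.0
    return flags, fraction
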