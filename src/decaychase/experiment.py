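"""Core in-memory container for one actinomycin-D chase experiment.

A chase experiment couples a gene x sample count matrix with per-gene
annotation (symbol, biotype, exonic length) and a sample sheet describing
genotype, subject (mouse), and minutes after transcription shut-off.
Time 0 denotes the anchor sample taken at ActD addition (1 h after LPS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ChaseExperiment", "ValidationError"]


class ValidationError(ValueError):
    """Raised when tables violate the chase-experiment contract."""


@dataclass
class ChaseExperiment:
    """Count matrix plus gene annotation plus sample sheet.

    Parameters
    ----------
    counts
        Gene x sample matrix of non-negative read counts, indexed by
        ``gene_id`` with one column per ``sample_id``.  Values may be
        floats when the matrix comes from a noise-free simulation.
    gene_annotation
        Indexed by ``gene_id`` with columns ``symbol``, ``biotype`` and
        ``length_bp`` (exonic length, strictly positive).
    sample_sheet
        Indexed by ``sample_id`` with columns ``genotype``, ``subject``
        and ``time_min`` (minutes after ActD; 0 is the anchor).
    """

    counts: pd.DataFrame
    gene_annotation: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        counts, annot, samples = self.counts, self.gene_annotation, self.sample_sheet
        for name, df in (("counts", counts), ("gene_annotation", annot), ("sample_sheet", samples)):
            if df.index.has_duplicates:
                dups = sorted(df.index[df.index.duplicated()].unique().tolist())
                raise ValidationError(f"{name}: duplicated identifiers {dups}")

        if set(counts.index) != set(annot.index):
            missing = set(counts.index) ^ set(annot.index)
            raise ValidationError(
                f"genes in counts and annotation are not a bijection; mismatched: {sorted(missing)[:10]}"
            )
        if set(counts.columns) != set(samples.index):
            missing = set(counts.columns) ^ set(samples.index)
            raise ValidationError(
                f"samples in counts and sample sheet are not a bijection; mismatched: {sorted(missing)[:10]}"
            )

        vals = counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.isnan(vals).any() or (vals < 0).any():
            raise ValidationError("counts must be non-negative and non-missing")

        for col in ("symbol", "biotype", "length_bp"):
            if col not in annot.columns:
                raise ValidationError(f"gene_annotation missing required column {col!r}")
        if (pd.to_numeric(annot["length_bp"], errors="coerce") <= 0).any() or annot["length_bp"].isna().any():
            bad = annot.index[~(pd.to_numeric(annot["length_bp"], errors="coerce") > 0)].tolist()
            raise ValidationError(f"length_bp must be strictly positive; offending genes: {bad[:10]}")

        for col in ("genotype", "subject", "time_min"):
            if col not in samples.columns:
                raise ValidationError(f"sample_sheet missing required column {col!r}")
        t = pd.to_numeric(samples["time_min"], errors="coerce")
        if t.isna().any() or (t < 0).any():
            bad = samples.index[t.isna() | (t < 0)].tolist()
            raise ValidationError(f"time_min must be a non-negative number; offending samples: {bad}")

        key = samples[["genotype", "subject", "time_min"]]
        dup_mask = key.duplicated(keep=False)
        if dup_mask.any():
            groups = samples[dup_mask].groupby(["genotype", "subject", "time_min"]).groups
            desc = "; ".join(
                f"(genotype={g}, subject={s}, time_min={tm}): samples {sorted(ix.tolist())}"
                for (g, s, tm), ix in groups.items()
            )
            raise ValidationError(f"duplicate (genotype, subject, time) samples: {desc}")

    # -- convenience ----------------------------------------------------
    @property
    def genotypes(self) -> list[str]:
        return list(pd.unique(self.sample_sheet["genotype"]))

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(pd.unique(pd.to_numeric(self.sample_sheet["time_min"])))

    def samples_for(self, genotype: str) -> pd.DataFrame:
        return self.sample_sheet[self.sample_sheet["genotype"] == genotype]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ChaseExperiment({self.counts.shape[0]} genes x {self.counts.shape[1]} samples, "
            f"genotypes={self.genotypes}, timepoints={self.timepoints.tolist()})"
        )
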