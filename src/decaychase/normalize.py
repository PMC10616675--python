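"""Library normalization, percent-remaining curves, and the gene filter cascade.

The chase design measures, per mouse, expression at a series of minutes
after actinomycin D.  Each gene's trajectory is expressed as the percent of
that same mouse's anchor (t = 0) value, so every retained gene/subject
curve starts at exactly 100.  Because transcription is shut off, total RNA
shrinks over the chase; any normalization that equalizes libraries
(fixed-depth scaling, median-of-ratios) therefore inflates slow-decaying
transcripts, which can apparently exceed 100% remaining.  That artifact is
modeled, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PercentRemainingCurves",
    "FilterReport",
    "size_factors",
    "normalized_per_kb",
    "fpkm",
    "percent_remaining",
    "apply_filters",
    "DEFAULT_EXCLUDED_GENES",
]

#: Genes removed a priori from the decay screen: the knocked-out family
#: members and one gene artefactually elevated downstream of the knockout.
DEFAULT_EXCLUDED_GENES = ("Zfp36", "Zfp36l1", "Zfp36l2", "Plekhg2")


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    Each sample's factor is the median, over genes nonzero in *all*
    samples, of the ratio of its count to the geometric-mean reference
    profile.  Factors are rescaled so their geometric mean is 1.
    """
    mat = counts.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("size_factors: no gene is nonzero in all samples")
    sub = mat[nonzero]
    log_ref = np.log(sub).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_ref, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_per_kb(counts: pd.DataFrame, lengths: pd.Series, factors: pd.Series | None = None) -> pd.DataFrame:
    """Normalized counts per kilobase: count / size_factor / (length_bp / 1000)."""
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"normalized_per_kb: missing lengths for genes {missing.tolist()[:10]}")
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    length_kb = lengths.reindex(counts.index).astype(float) / 1000.0
    return counts.div(factors.reindex(counts.columns), axis=1).div(length_kb, axis=0)


def fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million: count * 1e9 / (library_size * length_bp)."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        empty = lib.index[lib <= 0].tolist()
        raise ValueError(f"fpkm: empty libraries {empty}")
    length = lengths.reindex(counts.index).astype(float)
    if length.isna().any():
        raise ValueError("fpkm: missing lengths")
    return counts.mul(1e9).div(lib, axis=1).div(length, axis=0)


@dataclass
class PercentRemainingCurves:
    """Per gene x genotype x subject x timepoint percent-of-anchor values.

    ``data[genotype]`` is an array of shape ``(n_genes, n_subjects,
    n_timepoints)`` aligned with ``genes``, ``subjects[genotype]`` and
    ``timepoints``; missing observations (subject without a usable anchor)
    are NaN.  Values at t = 0 are exactly 100 wherever defined.
    """

    genes: pd.Index
    timepoints: np.ndarray
    subjects: dict[str, list]
    data: dict[str, np.ndarray]

    @property
    def genotypes(self) -> list[str]:
        return list(self.data)

    def mean(self, genotype: str) -> np.ndarray:
        """(n_genes, n_timepoints) mean over available subjects."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.data[genotype], axis=1)

    def sd(self, genotype: str) -> np.ndarray:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanstd(self.data[genotype], axis=1, ddof=1)

    def mean_curve(self, gene: str, genotype: str) -> pd.Series:
        i = self.genes.get_loc(gene)
        return pd.Series(self.mean(genotype)[i], index=self.timepoints, name=gene)

    def gene_array(self, gene: str, genotype: str) -> np.ndarray:
        """(n_subjects, n_timepoints) array for one gene."""
        return self.data[genotype][self.genes.get_loc(gene)]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for geno, arr in self.data.items():
            for si, subj in enumerate(self.subjects[geno]):
                for ti, t in enumerate(self.timepoints):
                    vals = arr[:, si, ti]
                    rows.append(
                        pd.DataFrame(
                            {
                                "gene_id": self.genes,
                                "genotype": geno,
                                "subject": subj,
                                "time_min": t,
                                "percent": vals,
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)


def percent_remaining(normalized: pd.DataFrame, samples: pd.DataFrame) -> PercentRemainingCurves:
    """Convert normalized expression to percent-of-anchor decay curves.

    For each subject, ``P_g(t) = 100 * x_g(t) / x_g(0)`` using that
    subject's own t = 0 sample.  Subjects with ``x_g(0) = 0`` yield NaN for
    that gene.  Every subject must have an anchor sample.
    """
    t = pd.to_numeric(samples["time_min"])
    timepoints = np.sort(t.unique())
    if timepoints[0] != 0:
        raise ValueError("percent_remaining: no t = 0 anchor samples present")
    genes = normalized.index
    data: dict[str, np.ndarray] = {}
    subjects: dict[str, list] = {}
    for geno, geno_samples in samples.groupby("genotype", sort=False):
        subj_ids = list(pd.unique(geno_samples["subject"]))
        arr = np.full((len(genes), len(subj_ids), len(timepoints)), np.nan)
        for si, subj in enumerate(subj_ids):
            rows = geno_samples[geno_samples["subject"] == subj]
            anchor = rows.index[pd.to_numeric(rows["time_min"]) == 0]
            if len(anchor) == 0:
                raise ValueError(f"percent_remaining: subject {subj!r} ({geno}) lacks a t = 0 anchor sample")
            x0 = normalized[anchor[0]].to_numpy(dtype=float)
            with np.errstate(divide="ignore", invalid="ignore"):
                for sample_id, tm in zip(rows.index, pd.to_numeric(rows["time_min"])):
                    ti = int(np.searchsorted(timepoints, tm))
                    vals = 100.0 * normalized[sample_id].to_numpy(dtype=float) / x0
                    vals[x0 == 0] = np.nan
                    arr[:, si, ti] = vals
        data[geno] = arr
        subjects[geno] = subj_ids
    return PercentRemainingCurves(genes=genes, timepoints=timepoints, subjects=subjects, data=data)


@dataclass
class FilterReport:
    """Per-gene retention fate with machine-readable exclusion reasons.

    ``table`` is indexed by gene with a boolean ``retained`` column and a
    ``reasons`` column holding a (possibly empty) tuple drawn from
    ``{non_mrna, excluded_gene, low_expression, non_decaying_control,
    undefined_t0}``.  A gene is retained iff its reason set is empty.
    """

    table: pd.DataFrame
    ceiling_time_used: float

    @property
    def retained_genes(self) -> pd.Index:
        return self.table.index[self.table["retained"]]

    def reasons_for(self, gene: str) -> tuple[str, ...]:
        return self.table.loc[gene, "reasons"]


def apply_filters(
    curves: PercentRemainingCurves,
    fpkm_matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    samples: pd.DataFrame,
    control_label: str,
    excluded_genes: tuple[str, ...] = DEFAULT_EXCLUDED_GENES,
    min_fpkm: float = 0.1,
    decay_ceiling: float = 85.0,
    ceiling_time: float = 120.0,
    mrna_biotypes: tuple[str, ...] = ("protein_coding", "mRNA"),
) -> FilterReport:
    """Apply the four-way gene filter cascade.

    A gene is retained iff it (1) is an mRNA biotype, (2) is not in the
    exclusion list (matched on identifier or symbol), (3) has mean control
    FPKM at t = 0 at or above ``min_fpkm``, (4) decays below
    ``decay_ceiling`` percent remaining on the control mean curve at
    ``ceiling_time`` (or the latest grid time at or before it), and (5) has
    a defined anchor in at least one control subject.  Reasons are computed
    independently on the full input, so the cascade is order-free.
    """
    genes = curves.genes
    annot = annotation.reindex(genes)

    is_mrna = annot["biotype"].isin(mrna_biotypes).to_numpy()
    excluded_set = {str(g) for g in excluded_genes}
    is_excluded = np.array(
        [gid in excluded_set or str(sym) in excluded_set for gid, sym in zip(genes, annot["symbol"])]
    )

    control_t0 = samples.index[
        (samples["genotype"] == control_label) & (pd.to_numeric(samples["time_min"]) == 0)
    ]
    mean_fpkm0 = fpkm_matrix.reindex(genes)[control_t0].mean(axis=1).to_numpy()

    grid = curves.timepoints
    usable = grid[grid <= ceiling_time]
    if len(usable) == 0:
        raise ValueError("apply_filters: no timepoint at or before ceiling_time")
    t_used = float(usable[-1])
    ti = int(np.searchsorted(grid, t_used))
    control_mean = curves.mean(control_label)
    p_ceiling = control_mean[:, ti]
    t0_defined = ~np.isnan(curves.mean(control_label)[:, 0])

    reasons = []
    for i in range(len(genes)):
        r = []
        if not is_mrna[i]:
            r.append("non_mrna")
        if is_excluded[i]:
            r.append("excluded_gene")
        if not t0_defined[i]:
            r.append("undefined_t0")
        elif mean_fpkm0[i] < min_fpkm:
            r.append("low_expression")
        if t0_defined[i] and not (p_ceiling[i] < decay_ceiling):
            r.append("non_decaying_control")
        reasons.append(tuple(r))

    table = pd.DataFrame(
        {"retained": [len(r) == 0 for r in reasons], "reasons": reasons}, index=genes
    )
    return FilterReport(table=table, ceiling_time_used=t_used)
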