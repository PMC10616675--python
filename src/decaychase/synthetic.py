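"""Generators for chase-count experiments, 3'-UTR sequences, and induction curves.

These emulate the study design the pipeline targets: two genotypes
(control first, knockout second), four mice per genotype, one library per
mouse per timepoint over roughly two hours of actinomycin-D chase.  Gene
abundance follows first-order decay ``a_g(t) = a_g(0) * exp(-k_g t)`` with
gene-specific half-lives (controls mostly 15-60 min); a configurable
fraction of genes is stabilized in the knockout (half-life multiplied by
``stabilization_factor``) and a fraction is effectively non-decaying in
all genotypes.  Counts carry negative-binomial replicate noise, and an
optional fixed-total-depth renormalization reproduces the apparent-increase
artifact for slow-decaying transcripts: because the RNA pool shrinks during
the chase, equalizing library totals inflates stable transcripts above
100% remaining.

Every generator is deterministic given its seed, and returns the ground
truth it drew so downstream recovery can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .experiment import ChaseExperiment
from .motifs import MOTIF_CLASSES

__all__ = [
    "DecaySimConfig",
    "SyntheticTruth",
    "PlantedSite",
    "simulate_chase",
    "simulate_utrs",
    "simulate_induction",
]

NON_MRNA_BIOTYPES = ("rRNA", "snoRNA", "miRNA", "lincRNA")


@dataclass(frozen=True)
class DecaySimConfig:
    """Generative parameters of one synthetic chase experiment.

    Half-lives are drawn log-normally (parameters on the log scale, in
    minutes); ``(3.4, 0.35)`` puts most control half-lives between 15 and
    60 min.  ``dispersion`` is the negative-binomial dispersion
    (var = mu + dispersion * mu^2); ``None`` turns replicate noise off
    entirely, yielding exact expected counts (floats).  With the default
    depth and gene number, mean counts around 1000 plus dispersion 0.01
    give roughly 10% CV per measurement.
    """

    n_genes: int = 2000
    genotypes: tuple[str, ...] = ("control", "ko")
    n_subjects_per_genotype: int = 4
    timepoints_min: tuple[float, ...] = (0, 15, 30, 45, 60, 90, 120)
    baseline_abundance_logmean: float = 3.0
    baseline_abundance_logsd: float = 1.0
    control_halflife_logmean: float = math.log(30.0)
    control_halflife_logsd: float = 0.35
    stabilized_fraction: float = 0.025
    stabilization_factor: float = 6.0
    stabilized_control_halflife: float | None = 20.0
    nondecaying_fraction: float = 0.2
    non_mrna_fraction: float = 0.05
    dispersion: float | Sequence[float] | None = 0.01
    library_depth: float = 2_000_000
    renormalize_to_fixed_depth: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_min, dtype=float)
        if len(t) < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints_min must be strictly increasing and start at 0")
        if self.n_subjects_per_genotype < 1:
            raise ValueError("need at least one subject per genotype")
        if self.stabilized_fraction + self.nondecaying_fraction > 1:
            raise ValueError("stabilized_fraction + nondecaying_fraction must be <= 1")
        if self.stabilization_factor < 1:
            raise ValueError("stabilization_factor must be >= 1 (1 means no effect)")
        if self.dispersion is not None:
            d = np.asarray(self.dispersion, dtype=float)
            if np.any(d <= 0):
                raise ValueError("dispersion must be positive (or None for noise off)")
        if len(self.genotypes) < 2:
            raise ValueError("need a control and at least one knockout genotype")


class PlantedSite(NamedTuple):
    motif_class: str
    start: int  # 1-based


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated experiment.

    ``decay`` has one row per gene x genotype with the decay rate
    ``k_per_min``, the implied half-life (``inf`` for non-decaying genes;
    t_half * k = ln 2 elsewhere), the expected anchor abundance, and the
    stabilized flag.  ``planted_sites`` is filled by :func:`simulate_utrs`.
    """

    decay: pd.DataFrame
    planted_sites: dict[str, list[PlantedSite]] = field(default_factory=dict)

    def halflife(self, gene: str, genotype: str) -> float:
        sub = self.decay
        row = sub[(sub["gene_id"] == gene) & (sub["genotype"] == genotype)]
        return float(row["halflife_min"].iloc[0])

    def stabilized_genes(self) -> list[str]:
        sub = self.decay[self.decay["stabilized"]]
        return sorted(sub["gene_id"].unique())

    def to_frame(self) -> pd.DataFrame:
        out = self.decay.copy()
        out["planted_sites"] = out["gene_id"].map(
            lambda g: ";".join(f"{c}@{s}" for c, s in self.planted_sites.get(g, []))
        )
        return out


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    d = np.asarray(dispersion, dtype=float)
    if d.ndim == 1:  # per-gene dispersion
        d = d[:, None]
    r = 1.0 / d
    p = r / (r + mu)
    return rng.negative_binomial(np.broadcast_to(r, mu.shape), p).astype(float)


def simulate_chase(config: DecaySimConfig) -> tuple[ChaseExperiment, SyntheticTruth]:
    """Draw one chase experiment and its ground truth.

    Expected abundance decays exponentially per genotype; per-library
    expected counts are the abundance-times-length profile scaled so each
    genotype's anchor library totals ``library_depth``.  Libraries at later
    timepoints therefore shrink as the pool decays — unless
    ``renormalize_to_fixed_depth`` rescales every column back to the fixed
    depth, which is exactly what creates the apparent-increase artifact.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = np.array([f"G{i:05d}" for i in range(n)])
    timepoints = np.asarray(config.timepoints_min, dtype=float)

    # gene roles: non-mRNA tag, non-decaying, stabilized (mRNA decaying only)
    biotype = np.full(n, "protein_coding", dtype=object)
    n_non_mrna = int(round(config.non_mrna_fraction * n))
    non_mrna_idx = rng.choice(n, size=n_non_mrna, replace=False)
    biotype[non_mrna_idx] = rng.choice(NON_MRNA_BIOTYPES, size=n_non_mrna)

    nondecaying = np.zeros(n, dtype=bool)
    n_nd = int(round(config.nondecaying_fraction * n))
    nondecaying[rng.choice(n, size=n_nd, replace=False)] = True

    eligible = np.flatnonzero(~nondecaying & (biotype == "protein_coding"))
    n_stab = int(round(config.stabilized_fraction * n))
    if n_stab > len(eligible):
        raise ValueError("stabilized_fraction too large for the available decaying mRNA genes")
    stabilized = np.zeros(n, dtype=bool)
    stabilized[rng.choice(eligible, size=n_stab, replace=False)] = True

    halflife_ctrl = rng.lognormal(config.control_halflife_logmean, config.control_halflife_logsd, n)
    if config.stabilized_control_halflife is not None:
        halflife_ctrl[stabilized] = config.stabilized_control_halflife
    halflife_ctrl[nondecaying] = np.inf

    baseline = rng.lognormal(config.baseline_abundance_logmean, config.baseline_abundance_logsd, n)
    lengths = np.maximum(200, np.round(rng.lognormal(math.log(1500.0), 0.5, n))).astype(int)

    control_label = config.genotypes[0]
    halflife = {control_label: halflife_ctrl}
    for geno in config.genotypes[1:]:
        h = halflife_ctrl.copy()
        h[stabilized] = halflife_ctrl[stabilized] * config.stabilization_factor
        halflife[geno] = h

    truth_rows = []
    for geno in config.genotypes:
        h = halflife[geno]
        with np.errstate(divide="ignore"):
            k = np.where(np.isinf(h), 0.0, math.log(2) / h)
        truth_rows.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "genotype": geno,
                    "k_per_min": k,
                    "halflife_min": h,
                    "baseline": baseline,
                    "stabilized": stabilized & (geno != control_label),
                }
            )
        )
    truth = SyntheticTruth(decay=pd.concat(truth_rows, ignore_index=True))

    # expected per-library counts, anchored so each genotype's t0 totals library_depth
    columns: dict[str, np.ndarray] = {}
    sample_rows = []
    for geno in config.genotypes:
        h = halflife[geno]
        k = np.where(np.isinf(h), 0.0, math.log(2) / h)
        profile0 = baseline * lengths / 1000.0
        scale = config.library_depth / profile0.sum()
        for subj in range(1, config.n_subjects_per_genotype + 1):
            for t in timepoints:
                mu = scale * profile0 * np.exp(-k * t)
                if config.dispersion is None:
                    counts = mu
                else:
                    counts = _nb_draw(rng, mu[:, None], config.dispersion)[:, 0]
                if config.renormalize_to_fixed_depth:
                    total = counts.sum()
                    if total > 0:
                        counts = counts * (config.library_depth / total)
                    if config.dispersion is not None:
                        counts = np.rint(counts)
                sample_id = f"{geno}_m{subj}_t{t:g}"
                columns[sample_id] = counts
                sample_rows.append({"sample_id": sample_id, "genotype": geno, "subject": f"m{subj}", "time_min": t})

    counts_df = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    annotation = pd.DataFrame(
        {"symbol": genes, "biotype": biotype, "length_bp": lengths},
        index=pd.Index(genes, name="gene_id"),
    )
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    experiment = ChaseExperiment(counts=counts_df, gene_annotation=annotation, sample_sheet=samples)
    return experiment, truth


def simulate_utrs(
    truth: SyntheticTruth,
    background_composition: dict[str, float] | None = None,
    utr_length_range: tuple[int, int] = (200, 600),
    site_prob_stabilized: float = 1.0,
    site_prob_other: float = 0.2,
    max_sites_per_gene: int = 3,
    seed: int = 0,
) -> dict[str, str]:
    """Draw one synthetic 3'-UTR per gene, planting AU-rich sites.

    Background bases are i.i.d. from ``background_composition`` (default
    mildly AU-rich); planted motifs overwrite the background at recorded,
    non-overlapping positions.  Stabilized genes receive at least one site
    with probability ``site_prob_stabilized``, other genes with
    ``site_prob_other``.  Planted classes and 1-based positions are stored
    in ``truth.planted_sites``; re-scanning the returned sequences is
    guaranteed to find every planted site.
    """
    comp = background_composition or {"A": 0.3, "C": 0.2, "G": 0.2, "U": 0.3}
    bases = list(comp)
    probs = np.asarray([comp[b] for b in bases], dtype=float)
    probs = probs / probs.sum()
    rng = np.random.default_rng(seed)
    lo, hi = utr_length_range
    class_names = list(MOTIF_CLASSES)

    gene_table = truth.decay.drop_duplicates("gene_id")
    stabilized = set(truth.stabilized_genes())
    utrs: dict[str, str] = {}
    truth.planted_sites = {}
    for gene in gene_table["gene_id"]:
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(bases, size=length, p=probs)
        p_site = site_prob_stabilized if gene in stabilized else site_prob_other
        planted: list[PlantedSite] = []
        if rng.random() < p_site:
            n_sites = int(rng.integers(1, max_sites_per_gene + 1))
            occupied: list[tuple[int, int]] = []
            for _ in range(n_sites):
                cls = class_names[rng.integers(len(class_names))]
                pattern = MOTIF_CLASSES[cls]
                if length < len(pattern):
                    raise ValueError(f"UTR of {gene} ({length} nt) too short for a {cls} site")
                for _attempt in range(50):
                    start0 = int(rng.integers(0, length - len(pattern) + 1))
                    span = (start0, start0 + len(pattern))
                    if all(span[1] <= a or span[0] >= b for a, b in occupied):
                        occupied.append(span)
                        seq[span[0] : span[1]] = list(pattern)
                        planted.append(PlantedSite(motif_class=cls, start=start0 + 1))
                        break
        utrs[gene] = "".join(seq)
        if planted:
            truth.planted_sites[gene] = sorted(planted, key=lambda s: s.start)
    return utrs


def simulate_induction(
    timepoints_h: Sequence[float],
    gene_params: pd.DataFrame,
    noise_cv: float = 0.1,
    n_replicates: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rise-and-fall induction curves with multiplicative noise.

    ``gene_params`` needs columns ``gene_id``, ``peak_time``, ``peak_fold``
    and ``decay_to_baseline`` (a shape exponent; larger values pull the
    curve back to baseline faster after the peak).  The noiseless mean is
    ``v(t) = 1 + (fold - 1) * ((t/tp) * exp(1 - t/tp))^s``, which starts at
    1, peaks at exactly ``fold`` at ``tp`` and relaxes toward baseline.
    Returns the observed long table (gene_id, time, mean, sd, n) and the
    noiseless truth table, whose trapezoid AUC is the reference value.
    """
    t = np.asarray(timepoints_h, dtype=float)
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing and include 0")
    rng = np.random.default_rng(seed)
    obs_rows, truth_rows = [], []
    for _, row in gene_params.iterrows():
        tp, fold, shape = float(row["peak_time"]), float(row["peak_fold"]), float(row["decay_to_baseline"])
        if not (t[0] <= tp <= t[-1]):
            raise ValueError(f"peak_time {tp} outside the grid span [{t[0]}, {t[-1]}]")
        with np.errstate(divide="ignore", invalid="ignore"):
            pulse = np.where(t > 0, (t / tp) * np.exp(1 - t / tp), 0.0)
        mean_curve = 1.0 + (fold - 1.0) * pulse**shape
        sigma = math.sqrt(math.log(1 + noise_cv**2))
        reps = mean_curve[None, :] * rng.lognormal(-(sigma**2) / 2, sigma, (n_replicates, len(t)))
        obs_rows.append(
            pd.DataFrame(
                {
                    "gene_id": row["gene_id"],
                    "time": t,
                    "mean": reps.mean(axis=0),
                    "sd": reps.std(axis=0, ddof=1),
                    "n": n_replicates,
                }
            )
        )
        truth_rows.append(pd.DataFrame({"gene_id": row["gene_id"], "time": t, "mean": mean_curve}))
    return pd.concat(obs_rows, ignore_index=True), pd.concat(truth_rows, ignore_index=True)
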