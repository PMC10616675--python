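"""Two-stage screen for stabilized transcripts in knockout-vs-control chase data.

Stage 1 performs, per gene, unpaired two-tailed t tests between genotypes
at every post-anchor timepoint and passes genes whose p-values fall below a
fixed cutoff (default 0.008) at a run of consecutive timepoints (default 3)
with the knockout above the control.  Stage 2 subjects stage-1 passers to a
mixed-design two-way repeated-measures ANOVA (between-subject genotype,
within-subject time, subject nested in genotype) with the
Greenhouse-Geisser sphericity correction, plus Sidak-adjusted per-timepoint
comparisons; genes are gated on the configured ANOVA term at alpha 0.05.
Survivors are ranked by the mean knockout-minus-control difference in
percent remaining at 60 and 120 min, and half-lives are read off the mean
curves by linear interpolation of the first downward crossing of 50%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .experiment import ChaseExperiment
from .normalize import (
    DEFAULT_EXCLUDED_GENES,
    FilterReport,
    PercentRemainingCurves,
    apply_filters,
    fpkm,
    normalized_per_kb,
    percent_remaining,
    size_factors,
)

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "HalfLife",
    "stage1_screen",
    "stage2_rm_anova",
    "mixed_rm_anova",
    "greenhouse_geisser_epsilon",
    "sidak_adjust",
    "rank_stabilized",
    "estimate_half_life",
    "run_screen",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Tuning knobs of the two-stage screen.

    ``stage1_alpha`` is applied as a fixed per-timepoint cutoff (a
    Bonferroni-style constant of roughly 0.05 spread over the post-anchor
    tests); raw p-values are always reported so any cutoff can be
    re-applied downstream.
    """

    stage1_alpha: float = 0.008
    stage1_window: int = 3
    stage1_test_variant: str = "equal_variance"  # or "welch"
    require_direction: bool = True
    stage2_alpha: float = 0.05
    stage2_gate_term: str = "interaction"  # or "genotype"
    rank_times: tuple[float, float] = (60.0, 120.0)
    normalization: str = "median_of_ratios"  # or "total_count", "none"
    min_fpkm: float = 0.1
    decay_ceiling: float = 85.0
    ceiling_time: float = 120.0
    excluded_genes: tuple[str, ...] = DEFAULT_EXCLUDED_GENES
    halflife_log_scale: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.stage1_alpha < 1 and 0 < self.stage2_alpha < 1):
            raise ValueError("alphas must lie in (0, 1)")
        if self.stage1_window < 1:
            raise ValueError("stage1_window must be >= 1")
        if self.stage1_test_variant not in ("equal_variance", "welch"):
            raise ValueError(f"unknown stage1_test_variant {self.stage1_test_variant!r}")
        if self.stage2_gate_term not in ("interaction", "genotype"):
            raise ValueError(f"unknown stage2_gate_term {self.stage2_gate_term!r}")


@dataclass(frozen=True)
class HalfLife:
    """A half-life in minutes, possibly right-censored at the grid maximum."""

    minutes: float
    censored: bool = False

    def __str__(self) -> str:
        return f">{self.minutes:g} min" if self.censored else f"{self.minutes:g} min"


# ----------------------------------------------------------------------
# Stage 1: consecutive-timepoint t tests
# ----------------------------------------------------------------------


def stage1_screen(
    curves: PercentRemainingCurves,
    pair: tuple[str, str],
    config: ScreenConfig = ScreenConfig(),
    genes: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-gene consecutive-timepoint t-test screen.

    Returns a frame indexed by gene with per-timepoint ``t_<t>`` and
    ``p_<t>`` columns for each post-anchor timepoint, a ``stage1_pass``
    flag, the first qualifying window start, and a ``skip_reason`` for
    genes that could not be tested (fewer than two subjects per group).
    The anchor timepoint is excluded: both groups are identically 100
    there by construction.
    """
    control, ko = pair
    for g in pair:
        if g not in curves.data:
            raise ValueError(f"genotype {g!r} absent from curves")
    gene_index = curves.genes if genes is None else genes
    sel = curves.genes.get_indexer(gene_index)
    grid = curves.timepoints
    post = grid[grid > 0]
    ti = np.searchsorted(grid, post)

    a = curves.data[control][sel][:, :, ti]  # (g, s, t)
    b = curves.data[ko][sel][:, :, ti]
    n_a = (~np.isnan(a)).sum(axis=1)
    n_b = (~np.isnan(b)).sum(axis=1)
    equal_var = config.stage1_test_variant == "equal_variance"
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, p_val = stats.ttest_ind(a, b, axis=1, equal_var=equal_var, nan_policy="omit")
        mean_a = np.nanmean(a, axis=1)
        mean_b = np.nanmean(b, axis=1)
    t_stat = np.asarray(t_stat, dtype=float)
    p_val = np.asarray(p_val, dtype=float)
    untestable = (n_a < 2) | (n_b < 2)
    p_val[untestable] = np.nan
    t_stat[untestable] = np.nan

    sig = (p_val < config.stage1_alpha) & ~np.isnan(p_val)
    if config.require_direction:
        sig &= mean_b > mean_a

    w = config.stage1_window
    n_t = sig.shape[1]
    pass_flag = np.zeros(len(gene_index), dtype=bool)
    window_start = np.full(len(gene_index), np.nan)
    if n_t >= w:
        windows = np.lib.stride_tricks.sliding_window_view(sig, w, axis=1).all(axis=2)
        pass_flag = windows.any(axis=1)
        first = np.argmax(windows, axis=1)
        window_start[pass_flag] = post[first[pass_flag]]

    out = pd.DataFrame(index=gene_index)
    for j, t in enumerate(post):
        out[f"t_{t:g}"] = t_stat[:, j]
        out[f"p_{t:g}"] = p_val[:, j]
    out["stage1_pass"] = pass_flag
    out["window_start_min"] = window_start
    out["skip_reason"] = np.where(untestable.all(axis=1), "fewer_than_2_subjects", "")
    out.loc[out["skip_reason"] != "", "stage1_pass"] = False
    return out


# ----------------------------------------------------------------------
# Stage 2: mixed-design repeated-measures ANOVA
# ----------------------------------------------------------------------


def greenhouse_geisser_epsilon(pooled_cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k within-subject covariance.

    Uses the double-centered covariance: eps = tr(S*)^2 / ((k-1) sum S*^2),
    clamped to the theoretical range [1/(k-1), 1].
    """
    k = pooled_cov.shape[0]
    if k < 2:
        return float("nan")
    s = np.asarray(pooled_cov, dtype=float)
    s_dc = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    denom = (k - 1) * np.sum(s_dc**2)
    if denom <= 0:
        return 1.0
    eps = np.trace(s_dc) ** 2 / denom
    return float(min(1.0, max(1.0 / (k - 1), eps)))


def mixed_rm_anova(groups: list[np.ndarray]) -> dict:
    """Split-plot ANOVA: between-subject group, within-subject time.

    ``groups`` holds one ``(n_subjects, k_timepoints)`` array per group
    with complete data (no NaN).  Returns the classical decomposition with
    F, degrees of freedom and p for the group, time and group x time terms,
    the Greenhouse-Geisser epsilon from the pooled within-group covariance
    of time levels, and epsilon-corrected p-values for the within-subject
    terms.  With a single time level the within-subject terms are NaN and
    the group term reduces to a one-way between-subjects ANOVA.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(np.isnan(g).any() for g in groups):
        raise ValueError("mixed_rm_anova requires complete data; drop incomplete subjects first")
    n_g = [g.shape[0] for g in groups]
    if any(n < 2 for n in n_g):
        raise ValueError("mixed_rm_anova requires at least 2 complete subjects per group")
    k = groups[0].shape[1]
    if any(g.shape[1] != k for g in groups):
        raise ValueError("all groups must share the time grid")
    G, N = len(groups), sum(n_g)

    y = np.concatenate(groups, axis=0)  # (N, k)
    grand_total = y.sum()
    cf = grand_total**2 / (N * k)
    ss_total = (y**2).sum() - cf
    subj_totals = y.sum(axis=1)
    ss_between_subj = (subj_totals**2).sum() / k - cf
    group_totals = np.array([g.sum() for g in groups])
    ss_group = (group_totals**2 / (np.array(n_g) * k)).sum() - cf
    ss_subj_within = ss_between_subj - ss_group

    out: dict = {"n_per_group": n_g, "k_timepoints": k}
    df_group, df_subj = G - 1, N - G
    ms_group = ss_group / df_group
    ms_subj = ss_subj_within / df_subj if df_subj > 0 else np.nan
    f_group = ms_group / ms_subj if ms_subj and ms_subj > 0 else np.nan
    out["genotype"] = {
        "F": float(f_group),
        "df1": df_group,
        "df2": df_subj,
        "p": float(stats.f.sf(f_group, df_group, df_subj)) if np.isfinite(f_group) else float("nan"),
    }

    if k < 2:
        out["time"] = out["interaction"] = {
            "F": float("nan"), "df1": 0, "df2": 0, "p": float("nan"), "p_gg": float("nan")
        }
        out["gg_epsilon"] = float("nan")
        return out

    time_totals = y.sum(axis=0)
    ss_time = (time_totals**2).sum() / N - cf
    cell_totals = np.stack([g.sum(axis=0) for g in groups])  # (G, k)
    ss_cells = (cell_totals**2 / np.array(n_g)[:, None]).sum() - cf
    ss_inter = ss_cells - ss_group - ss_time
    ss_err = ss_total - ss_between_subj - ss_time - ss_inter

    df_time = k - 1
    df_inter = (G - 1) * (k - 1)
    df_err = (N - G) * (k - 1)
    ms_err = ss_err / df_err

    pooled_cov = sum((n - 1) * np.cov(g, rowvar=False) for n, g in zip(n_g, groups)) / (N - G)
    eps = greenhouse_geisser_epsilon(np.atleast_2d(pooled_cov))
    out["gg_epsilon"] = eps

    for name, ss, df1 in (("time", ss_time, df_time), ("interaction", ss_inter, df_inter)):
        f = (ss / df1) / ms_err if ms_err > 0 else np.nan
        rec = {
            "F": float(f),
            "df1": df1,
            "df2": df_err,
            "p": float(stats.f.sf(f, df1, df_err)) if np.isfinite(f) else float("nan"),
        }
        rec["p_gg"] = (
            float(stats.f.sf(f, eps * df1, eps * df_err))
            if np.isfinite(f) and np.isfinite(eps)
            else float("nan")
        )
        out[name] = rec
    return out


def sidak_adjust(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Sidak multiplicity adjustment: p_adj = 1 - (1 - p)^m."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = int(np.sum(~np.isnan(p)))
    return 1.0 - (1.0 - p) ** m


def stage2_rm_anova(
    curves: PercentRemainingCurves,
    pair: tuple[str, str],
    config: ScreenConfig = ScreenConfig(),
    genes: pd.Index | None = None,
) -> pd.DataFrame:
    """Per-gene mixed-design RM-ANOVA over the full decay curve.

    The anchor timepoint is included as a within-subject level.  Subjects
    with any missing timepoint are dropped for that gene (recorded in
    ``n_control``/``n_ko``).  Sidak-adjusted per-timepoint genotype
    comparisons are computed over the post-anchor timepoints (the anchor is
    a constant 100 in both groups).  ``stage2_pass`` gates the configured
    ANOVA term (epsilon-corrected for within-subject terms) at
    ``stage2_alpha``.
    """
    control, ko = pair
    gene_index = curves.genes if genes is None else genes
    grid = curves.timepoints
    post = grid[grid > 0]
    rows = []
    for gene in gene_index:
        arr_c = curves.gene_array(gene, control)
        arr_k = curves.gene_array(gene, ko)
        comp_c = arr_c[~np.isnan(arr_c).any(axis=1)]
        comp_k = arr_k[~np.isnan(arr_k).any(axis=1)]
        rec: dict = {"gene_id": gene, "n_control": comp_c.shape[0], "n_ko": comp_k.shape[0]}
        if comp_c.shape[0] < 2 or comp_k.shape[0] < 2:
            rec["skip_reason"] = "fewer_than_2_complete_subjects"
            rec["stage2_pass"] = False
            rows.append(rec)
            continue
        an = mixed_rm_anova([comp_c, comp_k])
        rec.update(
            {
                "F_genotype": an["genotype"]["F"],
                "p_genotype": an["genotype"]["p"],
                "F_time": an["time"]["F"],
                "p_time": an["time"]["p"],
                "p_time_gg": an["time"].get("p_gg", np.nan),
                "F_interaction": an["interaction"]["F"],
                "p_interaction": an["interaction"]["p"],
                "p_interaction_gg": an["interaction"].get("p_gg", np.nan),
                "gg_epsilon": an["gg_epsilon"],
                "skip_reason": "",
            }
        )
        # per-timepoint comparisons, Sidak-adjusted over the post-anchor tests
        ti = np.searchsorted(grid, post)
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p_t = stats.ttest_ind(
                comp_c[:, ti], comp_k[:, ti], axis=0,
                equal_var=config.stage1_test_variant == "equal_variance",
            )
        p_adj = sidak_adjust(np.asarray(p_t, dtype=float), m=len(post))
        for t, pa in zip(post, p_adj):
            rec[f"p_sidak_{t:g}"] = pa
        gate_p = rec["p_genotype"] if config.stage2_gate_term == "genotype" else rec["p_interaction_gg"]
        rec["stage2_pass"] = bool(np.isfinite(gate_p) and gate_p < config.stage2_alpha)
        rows.append(rec)
    if not rows:
        return pd.DataFrame(
            columns=["n_control", "n_ko", "stage2_pass", "skip_reason", "gg_epsilon"],
            index=pd.Index([], name="gene_id"),
        )
    return pd.DataFrame(rows).set_index("gene_id")


# ----------------------------------------------------------------------
# Ranking and half-lives
# ----------------------------------------------------------------------


def rank_metric(
    curves: PercentRemainingCurves, pair: tuple[str, str], rank_times: tuple[float, ...]
) -> pd.Series:
    """Mean knockout-minus-control difference in mean percent remaining at rank_times."""
    grid = curves.timepoints
    missing = [t for t in rank_times if t not in grid]
    if missing:
        raise ValueError(f"rank_times {missing} absent from the timepoint grid {grid.tolist()}")
    ti = np.searchsorted(grid, np.asarray(rank_times, dtype=float))
    control, ko = pair
    diff = (curves.mean(ko)[:, ti] - curves.mean(control)[:, ti]).mean(axis=1)
    return pd.Series(diff, index=curves.genes, name="rank_metric")


def rank_stabilized(result_table: pd.DataFrame) -> list[str]:
    """Stabilized genes, descending by rank metric; ties break by identifier."""
    stab = result_table[result_table["stabilized"]]
    metric = stab["rank_metric"]
    return sorted(stab.index, key=lambda g: (-metric[g], str(g)))


def estimate_half_life(
    times: np.ndarray, percents: np.ndarray, log_scale: bool = False
) -> HalfLife:
    """First downward crossing of 50% remaining, linearly interpolated.

    Returns a censored value at the grid maximum when the curve never
    drops to 50 within the observed window.  A curve touching exactly 50
    at a grid point yields that grid point.
    """
    times = np.asarray(times, dtype=float)
    percents = np.asarray(percents, dtype=float)
    ok = ~np.isnan(percents)
    times, percents = times[ok], percents[ok]
    if len(times) == 0:
        raise ValueError("estimate_half_life: empty curve")
    below = percents <= 50.0
    if not below.any():
        return HalfLife(minutes=float(times[-1]), censored=True)
    i = int(np.argmax(below))
    if percents[i] == 50.0 or i == 0:
        return HalfLife(minutes=float(times[i]))
    t0, t1 = times[i - 1], times[i]
    p0, p1 = percents[i - 1], percents[i]
    if log_scale:
        f = (math.log(p0) - math.log(50.0)) / (math.log(p0) - math.log(p1))
    else:
        f = (p0 - 50.0) / (p0 - p1)
    return HalfLife(minutes=float(t0 + f * (t1 - t0)))


# ----------------------------------------------------------------------
# Orchestration
# ----------------------------------------------------------------------


@dataclass
class ScreenResult:
    """Full screen output: per-gene table plus intermediate objects."""

    table: pd.DataFrame
    curves: PercentRemainingCurves
    filter_report: FilterReport
    config: ScreenConfig
    pair: tuple[str, str]

    @property
    def stabilized_genes(self) -> list[str]:
        return rank_stabilized(self.table)


def run_screen(
    experiment: ChaseExperiment,
    pair: tuple[str, str],
    config: ScreenConfig = ScreenConfig(),
    site_flags: pd.Series | None = None,
    known_targets: pd.Series | None = None,
) -> ScreenResult:
    """Normalize -> curves -> filters -> stage 1 -> stage 2 -> rank -> half-lives.

    ``site_flags`` and ``known_targets`` are optional per-gene booleans
    merged into the output table (binding-site and literature-target
    columns of the supplementary-table layout).  Fully deterministic.
    """
    counts = experiment.counts
    lengths = experiment.gene_annotation["length_bp"]
    samples = experiment.sample_sheet
    control, ko = pair

    if config.normalization == "median_of_ratios":
        factors = size_factors(counts)
    elif config.normalization == "total_count":
        lib = counts.sum(axis=0)
        factors = lib / np.exp(np.mean(np.log(lib)))
    elif config.normalization == "none":
        factors = pd.Series(1.0, index=counts.columns)
    else:
        raise ValueError(f"unknown normalization {config.normalization!r}")

    norm = normalized_per_kb(counts, lengths, factors)
    curves = percent_remaining(norm, samples)
    fpkm_mat = fpkm(counts, lengths)
    report = apply_filters(
        curves,
        fpkm_mat,
        experiment.gene_annotation,
        samples,
        control_label=control,
        excluded_genes=config.excluded_genes,
        min_fpkm=config.min_fpkm,
        decay_ceiling=config.decay_ceiling,
        ceiling_time=config.ceiling_time,
    )
    retained = report.retained_genes

    s1 = stage1_screen(curves, pair, config, genes=retained)
    s1_pass = s1.index[s1["stage1_pass"]]
    s2 = stage2_rm_anova(curves, pair, config, genes=s1_pass)

    metric = rank_metric(curves, pair, config.rank_times)
    grid = curves.timepoints

    table = pd.DataFrame(index=retained)
    table.index.name = "gene_id"
    annot = experiment.gene_annotation
    table["symbol"] = annot.reindex(retained)["symbol"]
    table["has_TTP_site"] = (
        site_flags.reindex(retained).fillna(False).astype(bool) if site_flags is not None else pd.NA
    )
    table["known_target"] = (
        known_targets.reindex(retained).fillna(False).astype(bool) if known_targets is not None else pd.NA
    )
    sel = curves.genes.get_indexer(retained)
    for geno, tag in ((control, "control"), (ko, "ko")):
        m, s = curves.mean(geno)[sel], curves.sd(geno)[sel]
        for j, t in enumerate(grid):
            table[f"{tag}_mean_{t:g}"] = m[:, j]
            table[f"{tag}_sd_{t:g}"] = s[:, j]
    for col in s1.columns:
        table[col] = s1[col]
    for col in s2.columns:
        table[col] = s2.reindex(retained)[col]
    if "stage2_pass" in table.columns:
        table["stage2_pass"] = table["stage2_pass"].map(lambda v: bool(v) if v == v else False)
    else:
        table["stage2_pass"] = False
    table["rank_metric"] = metric.reindex(retained)
    table["stabilized"] = table["stage1_pass"] & table["stage2_pass"]

    hl_c, hl_k, hl_c_cens, hl_k_cens = [], [], [], []
    mc, mk = curves.mean(control)[sel], curves.mean(ko)[sel]
    for i in range(len(retained)):
        h_c = estimate_half_life(grid, mc[i], log_scale=config.halflife_log_scale)
        h_k = estimate_half_life(grid, mk[i], log_scale=config.halflife_log_scale)
        hl_c.append(h_c.minutes)
        hl_c_cens.append(h_c.censored)
        hl_k.append(h_k.minutes)
        hl_k_cens.append(h_k.censored)
    table["half_life_control_min"] = hl_c
    table["half_life_control_censored"] = hl_c_cens
    table["half_life_ko_min"] = hl_k
    table["half_life_ko_censored"] = hl_k_cens

    return ScreenResult(table=table, curves=curves, filter_report=report, config=config, pair=pair)
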