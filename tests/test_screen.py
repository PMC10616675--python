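"""Two-stage stabilization screen: t-test stage, mixed RM-ANOVA, ranking, half-lives."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from decaychase import (
    DecaySimConfig,
    HalfLife,
    ScreenConfig,
    estimate_half_life,
    greenhouse_geisser_epsilon,
    mixed_rm_anova,
    rank_stabilized,
    run_screen,
    sidak_adjust,
    simulate_chase,
    stage1_screen,
    stage2_rm_anova,
)
from conftest import make_curves

GRID = np.array([0.0, 15.0, 30.0, 45.0, 60.0, 90.0, 120.0])


def curves_from_profiles(control_profile, ko_profile, sd=2.0, n=4, seed=0, genes=("g",)):
    """Per-subject curves = profile + N(0, sd) noise at post-anchor points."""
    rng = np.random.default_rng(seed)

    def group(profile):
        arr = np.tile(np.asarray(profile, dtype=float), (n, 1))
        arr[:, 1:] += rng.normal(0, sd, (n, arr.shape[1] - 1))
        arr[:, 0] = 100.0
        return arr

    control = {g: group(control_profile) for g in genes}
    ko = {g: group(ko_profile) for g in genes}
    return make_curves(GRID, control, ko, genes=list(genes))


class TestStage1:
    def test_identical_groups_never_pass(self):
        profile = [100, 80, 60, 45, 35, 25, 18]
        curves = curves_from_profiles(profile, profile, sd=3, seed=1)
        out = stage1_screen(curves, ("control", "ko"))
        assert not out["stage1_pass"].any()

    def test_separated_groups_pass_with_expected_window(self):
        control = [100, 70, 50, 35, 25, 15, 10]
        ko = [100, 97, 95, 93, 90, 88, 85]
        curves = curves_from_profiles(control, ko, sd=2, n=4, seed=2)
        out = stage1_screen(curves, ("control", "ko"))
        assert bool(out.loc["g", "stage1_pass"])
        assert out.loc["g", "window_start_min"] == 15.0
        # independent check of one timepoint's p-value against a direct t-test
        a = curves.gene_array("g", "control")[:, 2]
        b = curves.gene_array("g", "ko")[:, 2]
        nx, ny = len(a), len(b)
        sp = math.sqrt(((nx - 1) * a.var(ddof=1) + (ny - 1) * b.var(ddof=1)) / (nx + ny - 2))
        t_manual = (a.mean() - b.mean()) / (sp * math.sqrt(1 / nx + 1 / ny))
        p_manual = 2 * stats.t.sf(abs(t_manual), nx + ny - 2)
        assert out.loc["g", "p_30"] == pytest.approx(p_manual, rel=1e-10)
        assert p_manual < 1e-4

    def test_nonconsecutive_significance_fails_window(self):
        # KO above control only at 15, 45 and 120 min; equal elsewhere
        base = np.array([100, 60, 45, 35, 28, 20, 15.0])
        ko = base.copy()
        ko[[1, 3, 6]] += 40
        control = {"g": np.tile(base, (4, 1)) + np.random.default_rng(3).normal(0, 0.5, (4, 7))}
        ko_arr = {"g": np.tile(ko, (4, 1)) + np.random.default_rng(4).normal(0, 0.5, (4, 7))}
        curves = make_curves(GRID, control, ko_arr)
        out = stage1_screen(curves, ("control", "ko"))
        sig = [out.loc["g", f"p_{t:g}"] < 0.008 for t in GRID[1:]]
        assert sig[0] and sig[2] and sig[5] and not (sig[1] or sig[3] or sig[4])
        assert not out.loc["g", "stage1_pass"]

    def test_direction_requirement(self):
        control = [100, 97, 95, 93, 90, 88, 85]  # control above KO: destabilized
        ko = [100, 70, 50, 35, 25, 15, 10]
        curves = curves_from_profiles(control, ko, sd=2, seed=5)
        assert not stage1_screen(curves, ("control", "ko"))["stage1_pass"].any()
        cfg = ScreenConfig(require_direction=False)
        assert stage1_screen(curves, ("control", "ko"), cfg)["stage1_pass"].all()

    def test_alpha_monotonicity(self):
        cfg = DecaySimConfig(n_genes=150, seed=11, stabilized_fraction=0.1)
        exp, _ = simulate_chase(cfg)
        from decaychase import normalized_per_kb, percent_remaining, size_factors

        norm = normalized_per_kb(exp.counts, exp.gene_annotation["length_bp"], size_factors(exp.counts))
        curves = percent_remaining(norm, exp.sample_sheet)
        loose = stage1_screen(curves, ("control", "ko"), ScreenConfig(stage1_alpha=0.008))
        tight = stage1_screen(curves, ("control", "ko"), ScreenConfig(stage1_alpha=0.0008))
        assert set(tight.index[tight["stage1_pass"]]) <= set(loose.index[loose["stage1_pass"]])

    def test_fewer_than_two_subjects_skipped(self):
        control = {"g": np.array([[100, 50, 25, 12, 6, 3, 1.0]])}  # one subject
        ko = {"g": np.tile([100, 95, 90, 88, 85, 80, 75.0], (4, 1))}
        curves = make_curves(GRID, control, ko)
        out = stage1_screen(curves, ("control", "ko"))
        assert out.loc["g", "skip_reason"] == "fewer_than_2_subjects"
        assert not out.loc["g", "stage1_pass"]


class TestMixedAnova:
    def test_f_equals_t_squared_at_single_timepoint(self):
        rng = np.random.default_rng(8)
        a = rng.normal(40, 6, (5, 1))
        b = rng.normal(55, 6, (6, 1))
        res = mixed_rm_anova([a, b])
        t, p = stats.ttest_ind(a[:, 0], b[:, 0], equal_var=True)
        assert abs(res["genotype"]["F"] - t**2) / t**2 < 1e-8
        assert res["genotype"]["p"] == pytest.approx(p, rel=1e-8)

    def test_epsilon_is_one_for_two_time_levels(self):
        rng = np.random.default_rng(9)
        res = mixed_rm_anova([rng.normal(50, 5, (4, 2)), rng.normal(60, 5, (4, 2))])
        assert res["gg_epsilon"] == 1.0
        assert res["time"]["p_gg"] == pytest.approx(res["time"]["p"])

    def test_epsilon_bounds_hold(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            k = int(rng.integers(2, 8))
            res = mixed_rm_anova([rng.normal(0, 1, (4, k)), rng.normal(0, 1, (4, k))])
            assert 1.0 / (k - 1) - 1e-12 <= res["gg_epsilon"] <= 1.0 + 1e-12

    def test_epsilon_matches_eigenvalue_oracle(self):
        """Double-centered-trace epsilon equals the eigenvalue formula."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            k = 5
            g1, g2 = rng.normal(0, 1, (6, k)), rng.normal(0, 1, (5, k))
            s = (5 * np.cov(g1, rowvar=False) + 4 * np.cov(g2, rowvar=False)) / 9
            c = np.eye(k) - 1.0 / k
            lam = np.linalg.eigvalsh(c @ s @ c)
            eps_oracle = lam.sum() ** 2 / ((k - 1) * np.sum(lam**2))
            assert greenhouse_geisser_epsilon(s) == pytest.approx(max(1 / (k - 1), min(1, eps_oracle)), rel=1e-10)

    def test_epsilon_near_one_under_compound_symmetry(self):
        """Compound-symmetric covariance satisfies sphericity; mean eps-hat is
        close to its small-sample expectation estimated by brute-force simulation."""
        rng = np.random.default_rng(12)
        k, n, rho, reps = 4, 8, 0.5, 400
        cov = np.full((k, k), rho) + (1 - rho) * np.eye(k)
        chol = np.linalg.cholesky(cov)
        eps_impl, eps_oracle = [], []
        c = np.eye(k) - 1.0 / k
        for _ in range(reps):
            g1 = rng.standard_normal((n, k)) @ chol.T
            g2 = rng.standard_normal((n, k)) @ chol.T
            res = mixed_rm_anova([g1, g2])
            eps_impl.append(res["gg_epsilon"])
            s = ((n - 1) * np.cov(g1, rowvar=False) + (n - 1) * np.cov(g2, rowvar=False)) / (2 * n - 2)
            lam = np.linalg.eigvalsh(c @ s @ c)
            eps_oracle.append(min(1.0, lam.sum() ** 2 / ((k - 1) * np.sum(lam**2))))
        assert abs(np.mean(eps_impl) - np.mean(eps_oracle)) < 0.05

    def test_matches_pingouin_mixed_anova(self):
        """F and uncorrected p of all three terms agree with an established
        independent implementation on a fixed dataset."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(13)
        gc, gk = rng.normal(50, 10, (4, 6)), rng.normal(62, 10, (4, 6))
        res = mixed_rm_anova([gc, gk])
        rows = [
            {"subj": f"{lab}{s}", "group": lab, "time": t, "y": arr[s, t]}
            for lab, arr in (("c", gc), ("k", gk))
            for s in range(4)
            for t in range(6)
        ]
        aov = pg.mixed_anova(
            data=pd.DataFrame(rows), dv="y", within="time", subject="subj", between="group"
        ).set_index("Source")
        assert res["genotype"]["F"] == pytest.approx(aov.loc["group", "F"], rel=1e-10)
        assert res["time"]["F"] == pytest.approx(aov.loc["time", "F"], rel=1e-10)
        assert res["interaction"]["F"] == pytest.approx(aov.loc["Interaction", "F"], rel=1e-10)
        assert res["time"]["p"] == pytest.approx(aov.loc["time", "p_unc"], rel=1e-8)

    def test_null_gate_term_calibration(self):
        """With no genotype effect the interaction gate rejects at about alpha."""
        rng = np.random.default_rng(14)
        alpha, reps = 0.05, 800
        rejections = 0
        for _ in range(reps):
            g1 = rng.normal(50, 8, (4, 5))
            g2 = rng.normal(50, 8, (4, 5))
            res = mixed_rm_anova([g1, g2])
            rejections += res["interaction"]["p_gg"] < alpha
        rate = rejections / reps
        assert rate < alpha + 0.025  # GG correction is conservative under sphericity

    def test_requires_two_subjects_and_complete_data(self):
        with pytest.raises(ValueError, match="2 complete subjects|at least 2"):
            mixed_rm_anova([np.zeros((1, 3)), np.zeros((4, 3))])
        with pytest.raises(ValueError, match="complete"):
            mixed_rm_anova([np.array([[1.0, np.nan]]), np.zeros((4, 2))])

    def test_stage2_on_curves_and_sidak(self):
        control = [100, 70, 50, 35, 25, 15, 10]
        ko = [100, 97, 95, 93, 90, 88, 85]
        curves = curves_from_profiles(control, ko, sd=2, seed=15)
        out = stage2_rm_anova(curves, ("control", "ko"))
        assert bool(out.loc["g", "stage2_pass"])
        assert out.loc["g", "p_interaction_gg"] < 0.05
        assert 1.0 / 6 <= out.loc["g", "gg_epsilon"] <= 1.0
        # Sidak adjustment is monotone and conservative vs raw p
        for t in GRID[1:]:
            assert out.loc["g", f"p_sidak_{t:g}"] >= 0  # present
        np.testing.assert_allclose(sidak_adjust(np.array([0.01]), m=6), [1 - 0.99**6])


class TestRankingAndHalfLife:
    def test_rank_by_mean_difference(self):
        table = pd.DataFrame(
            {"stabilized": [True, True], "rank_metric": [(30 + 40) / 2, (10 + 80) / 2]},
            index=pd.Index(["A", "B"], name="gene_id"),
        )
        assert rank_stabilized(table) == ["B", "A"]

    def test_rank_ties_break_lexicographically(self):
        table = pd.DataFrame(
            {"stabilized": [True, True, False], "rank_metric": [35.0, 35.0, 99.0]},
            index=pd.Index(["zz", "aa", "skip"], name="gene_id"),
        )
        assert rank_stabilized(table) == ["aa", "zz"]

    def test_halflife_interpolation_of_exponential(self):
        curve = 100 * np.exp(-math.log(2) / 20 * GRID)
        hl = estimate_half_life(GRID, curve)
        assert not hl.censored and abs(hl.minutes - 20) <= 1

    def test_flat_curve_censored(self):
        hl = estimate_half_life(GRID, np.full(len(GRID), 100.0))
        assert hl == HalfLife(minutes=120.0, censored=True)
        assert str(hl) == ">120 min"

    def test_exact_grid_crossing(self):
        hl = estimate_half_life(np.array([0.0, 30.0, 60.0]), np.array([100.0, 50.0, 25.0]))
        assert hl.minutes == 30.0 and not hl.censored

    def test_log_scale_interpolation_recovers_exponential_exactly(self):
        curve = 100 * np.exp(-math.log(2) / 20 * GRID)
        hl = estimate_half_life(GRID, curve, log_scale=True)
        assert hl.minutes == pytest.approx(20.0, rel=1e-12)

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_half_life(np.array([]), np.array([]))


class TestRunScreen:
    def test_recovery_and_schema_on_small_simulation(self):
        cfg = DecaySimConfig(n_genes=400, seed=21)
        exp, truth = simulate_chase(cfg)
        result = run_screen(exp, ("control", "ko"))
        called = set(result.stabilized_genes)
        planted = set(truth.stabilized_genes())
        assert len(called & planted) >= 0.8 * len(planted)
        assert len(called - planted) <= max(1, 0.1 * len(called))
        # supplementary-table layout
        for col in (
            "symbol",
            "control_mean_0",
            "control_sd_120",
            "ko_mean_60",
            "p_60",
            "stage1_pass",
            "gg_epsilon",
            "p_interaction_gg",
            "rank_metric",
            "half_life_control_min",
            "half_life_ko_min",
            "stabilized",
        ):
            assert col in result.table.columns

    def test_decisions_invariant_to_gene_and_sample_order(self):
        cfg = DecaySimConfig(n_genes=120, seed=22, stabilized_fraction=0.05)
        exp, _ = simulate_chase(cfg)
        base = run_screen(exp, ("control", "ko"))
        rng = np.random.default_rng(0)
        gshuf = rng.permutation(exp.counts.index)
        sshuf = rng.permutation(exp.counts.columns)
        from decaychase import ChaseExperiment

        shuffled = ChaseExperiment(
            counts=exp.counts.loc[gshuf, sshuf],
            gene_annotation=exp.gene_annotation.loc[gshuf],
            sample_sheet=exp.sample_sheet.loc[sshuf],
        )
        perm = run_screen(shuffled, ("control", "ko"))
        assert set(base.stabilized_genes) == set(perm.stabilized_genes)
        assert set(base.filter_report.retained_genes) == set(perm.filter_report.retained_genes)

    def test_rank_times_must_be_on_grid(self):
        cfg = DecaySimConfig(n_genes=40, seed=23, timepoints_min=(0, 30, 60))
        exp, _ = simulate_chase(cfg)
        with pytest.raises(ValueError, match="rank_times"):
            run_screen(exp, ("control", "ko"), ScreenConfig(rank_times=(60.0, 120.0), ceiling_time=60.0))
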