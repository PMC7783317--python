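import numpy as np
import pandas as pd
import pytest

from metasieve import (
    EffectTableError,
    FilterPolicy,
    SyntheticConfig,
    cluster_robust_ci,
    compare_filtered_full,
    fit_three_level_reml,
    generate_literature,
    i_squared,
    prediction_interval,
)
from metasieve.meta import reml_neg2_loglik


def _frame(papers):
    """papers: list of (paper_id, [(r, n), ...])"""
    rows = []
    for pid, effects in papers:
        for r, n in effects:
            rows.append((pid, "1", "M", r, n, False, False, False))
    return pd.DataFrame(
        rows, columns=["paper_id", "study_id", "measure", "r", "n", "overfit", "team_level", "ghost"]
    )


def _grid_reml_oracle(z, v):
    """Brute-force profile-REML for a two-level model (one effect per study).

    Refined grid search over tau^2; mu is GLS in closed form.  Independent
    of the package optimizer.
    """

    def neg2ll(t2):
        w = 1.0 / (t2 + v)
        mu = np.sum(w * z) / np.sum(w)
        return np.sum(np.log(t2 + v)) + np.log(np.sum(w)) + np.sum(w * (z - mu) ** 2)

    lo, hi = 0.0, 4.0 * max(np.var(z), 0.1)
    for _ in range(6):
        grid = np.linspace(lo, hi, 201)
        vals = [neg2ll(t) for t in grid]
        i = int(np.argmin(vals))
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    t2 = 0.5 * (lo + hi)
    w = 1.0 / (t2 + v)
    return np.sum(w * z) / np.sum(w), np.sqrt(t2)


class TestREMLFit:
    def test_degenerate_identical_effects(self):
        df = _frame([("P1", [(0.3, 24), (0.3, 24)]), ("P2", [(0.3, 24)]), ("P3", [(0.3, 24)])])
        fit = fit_three_level_reml(df)
        assert fit.tau1 == pytest.approx(0.0, abs=1e-4)
        assert fit.tau2 == pytest.approx(0.0, abs=1e-4)
        assert fit.mu_z == pytest.approx(np.arctanh(0.3), abs=1e-8)

    def test_single_cluster_refused(self):
        df = _frame([("P1", [(0.3, 24), (0.4, 30)])])
        with pytest.raises(EffectTableError):
            fit_three_level_reml(df)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equivalence_with_grid_search_oracle(self, seed):
        """One effect per study, tau2 pinned at 0: REML matches a brute-force
        profile-likelihood grid within 1e-4 on mu and 1e-3 on tau."""
        rng = np.random.default_rng(seed)
        m = 8
        n = rng.integers(10, 60, m)
        true_z = rng.normal(0.3, 0.2, m)
        z = true_z + rng.standard_normal(m) / np.sqrt(n - 3)
        df = _frame([(f"P{i}", [(float(np.tanh(z[i])), int(n[i]))]) for i in range(m)])
        fit = fit_three_level_reml(df, fix_tau2=0.0)
        mu_o, tau_o = _grid_reml_oracle(np.arctanh(df["r"].to_numpy()), 1.0 / (df["n"].to_numpy() - 3))
        assert fit.mu_z == pytest.approx(mu_o, abs=1e-4)
        assert fit.tau1 == pytest.approx(tau_o, abs=1e-3)

    def test_objective_at_optimum_not_beaten_nearby(self, literature):
        """The returned components sit at a local REML minimum."""
        from metasieve.meta import _prepare

        fit = fit_three_level_reml(literature)
        z, v, codes, starts = _prepare(literature)
        f0 = reml_neg2_loglik(fit.tau1**2, fit.tau2**2, z, v, starts)
        assert f0 == pytest.approx(fit.neg2_loglik, abs=1e-9)
        eps = 1e-3
        for d1, d2 in [(eps, 0), (0, eps), (-eps, 0), (0, -eps)]:
            t1 = fit.tau1**2 + d1
            t2 = fit.tau2**2 + d2
            if t1 < 0 or t2 < 0:
                continue
            assert reml_neg2_loglik(t1, t2, z, v, starts) >= f0 - 1e-7

    def test_weight_conservation_balanced_clusters(self):
        """With tau2=0 and balanced clusters, mu is a convex combination of
        cluster means."""
        df = _frame(
            [
                ("P1", [(0.2, 30), (0.25, 30)]),
                ("P2", [(0.45, 30), (0.4, 30)]),
                ("P3", [(0.1, 30), (0.15, 30)]),
            ]
        )
        fit = fit_three_level_reml(df, fix_tau2=0.0)
        cluster_means = np.arctanh(df["r"].to_numpy()).reshape(3, 2).mean(axis=1)
        assert cluster_means.min() - 1e-10 <= fit.mu_z <= cluster_means.max() + 1e-10

    def test_back_transform_consistency(self, literature):
        fit = fit_three_level_reml(literature)
        assert fit.mu_r == pytest.approx(np.tanh(fit.mu_z))
        assert fit.ci_r == pytest.approx(tuple(np.tanh(fit.ci_z)))
        assert fit.pi_r == pytest.approx(tuple(np.tanh(fit.pi_z)))


class TestRobustInference:
    def test_df_bounded_by_clusters_minus_one(self, literature):
        fit = fit_three_level_reml(literature)
        assert fit.df_robust <= fit.n_clusters - 1

    def test_robust_close_to_model_se_when_model_holds(self):
        """Balanced equal-variance clusters with tau2=0: the sandwich agrees
        with the model SE within 15% (simulation sanity bound)."""
        rng = np.random.default_rng(42)
        ratios = []
        for _ in range(30):
            m, k, n = 12, 3, 40
            u = rng.normal(0, 0.15, m)
            papers = []
            for i in range(m):
                z = 0.3 + u[i] + rng.standard_normal(k) / np.sqrt(n - 3)
                papers.append((f"P{i}", [(float(np.tanh(zz)), n) for zz in z]))
            fit = fit_three_level_reml(_frame(papers), fix_tau2=0.0)
            ratios.append(fit.se_robust / fit.se_model)
        assert abs(np.mean(ratios) - 1.0) < 0.15

    def test_cluster_robust_ci_function_matches_fit(self, literature):
        fit = fit_three_level_reml(literature)
        ci = cluster_robust_ci(fit, literature)
        assert ci == pytest.approx(fit.ci_r, abs=1e-10)


class TestPredictionInterval:
    def test_contains_ci(self, literature):
        fit = fit_three_level_reml(literature)
        assert fit.pi_r[0] < fit.ci_r[0] and fit.ci_r[1] < fit.pi_r[1]

    def test_collapses_without_heterogeneity(self):
        df = _frame([(f"P{i}", [(0.3, 50)]) for i in range(6)])
        fit = fit_three_level_reml(df)
        pi = prediction_interval(fit)
        # tau=0: PI = mu +/- t_pi_df * se, CI = mu +/- t_satt * se; same up to df convention
        assert pi[0] == pytest.approx(fit.ci_r[0], abs=0.02)
        assert pi[1] == pytest.approx(fit.ci_r[1], abs=0.02)

    def test_covers_new_true_effects(self, replicate_harness):
        """>= 93% of newly simulated true effects fall inside the 95% PI."""
        _, rows = replicate_harness
        assert rows["pi_frac"].mean() >= 0.93


class TestISquared:
    def test_zero_without_heterogeneity(self, literature):
        fit = fit_three_level_reml(literature)
        zero = fit.__class__(**{**fit.__dict__, "tau1": 0.0, "tau2": 0.0})
        assert i_squared(zero, literature) == 0.0

    def test_increasing_in_tau(self, literature):
        fit = fit_three_level_reml(literature)
        vals = []
        for scale in (0.5, 1.0, 2.0):
            f = fit.__class__(**{**fit.__dict__, "tau1": fit.tau1 * scale, "tau2": fit.tau2 * scale})
            vals.append(i_squared(f, literature))
        assert vals[0] < vals[1] < vals[2]
        assert 0 <= vals[2] <= 100


class TestComparison:
    def test_no_filtering_gives_type_m_one(self):
        # every effect significant -> filtered mean == mean of all effects;
        # compare against the model mean of the same homogeneous effects
        df = _frame([(f"P{i}", [(0.6, 50)]) for i in range(5)])
        report = compare_filtered_full(df)
        assert report.type_m == pytest.approx(1.0, abs=1e-6)
        assert report.percent_higher == pytest.approx(0.0, abs=1e-4)

    def test_null_literature_filtered_mean_floored(self):
        """mu=0 literature: the filter's survivors average above the marginal
        guaranteed minimum while the full model stays near zero."""
        cfg = SyntheticConfig(mu_z=0.0, tau1=0.05, tau2=0.02, n_papers=60)
        df = generate_literature(cfg, seed=90)
        report = compare_filtered_full(df)
        from metasieve import critical_r

        if np.isfinite(report.filtered_mean_r):
            floor = critical_r(int(df["n"].max()), 0.10)
            assert report.filtered_mean_r >= floor
        assert abs(report.full_mean_r) < 0.08

    def test_identity_between_ratio_and_percent(self, literature):
        report = compare_filtered_full(literature)
        assert report.type_m == pytest.approx(1.0 + report.percent_higher / 100.0)
        assert set(report.per_measure["measure"]) <= {"SAGAT", "SPAM", "EndOfTrial"}


class TestParameterRecovery:
    def test_median_estimates_within_ten_percent(self, replicate_harness):
        """Median REML estimates across 200 literatures within 10% of truth."""
        truth, rows = replicate_harness
        sub = rows.iloc[:200]
        assert np.median(sub["mu_z"]) == pytest.approx(truth.mu_z, rel=0.10)
        assert np.median(sub["tau1"]) == pytest.approx(truth.tau1, rel=0.10)
        assert np.median(sub["tau2"]) == pytest.approx(truth.tau2, rel=0.10)

    def test_convergence_flag(self, replicate_harness):
        _, rows = replicate_harness
        assert rows["converged"].all()
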