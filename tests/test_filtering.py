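import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from metasieve import (
    EffectTableError,
    FilterPolicy,
    boundary_curve,
    classify_effects,
    critical_r,
    filter_dataset,
    filtered_mean,
    measure_level_filtered_mean,
    measure_level_filtered_means,
    predictiveness_score,
    r_p_value,
    score_table,
)

POLICY = FilterPolicy()


def _group(rs, n=30, paper="P1", measure="SAGAT"):
    return pd.DataFrame(
        {
            "paper_id": paper,
            "study_id": "1",
            "measure": measure,
            "r": rs,
            "n": n,
            "overfit": False,
            "team_level": False,
            "ghost": False,
        }
    )


class TestCriticalR:
    def test_matches_numeric_inversion(self):
        """Closed form agrees with numerically inverting the p-value."""
        for n, alpha in [(24, 0.05), (24, 0.10), (10, 0.05), (100, 0.01)]:
            rc = critical_r(n, alpha)
            root = optimize.brentq(lambda r: r_p_value(r, n, "one_sided_positive") - alpha, 1e-9, 1 - 1e-9)
            assert rc == pytest.approx(root, abs=1e-9)

    def test_value_at_median_sample_size(self):
        assert critical_r(24, 0.05) == pytest.approx(0.3438, abs=5e-4)

    def test_monotone_in_n_and_alpha(self):
        n = np.arange(5, 200)
        assert np.all(np.diff(critical_r(n, 0.05)) < 0)
        assert np.all(critical_r(n, 0.10) < critical_r(n, 0.05))

    def test_domain(self):
        with pytest.raises(EffectTableError):
            critical_r(3, 0.05)


class TestClassification:
    def test_negative_always_nonsignificant(self):
        for n in (5, 24, 500):
            assert classify_effects(-0.40, n)[0] == "nonsignificant"

    def test_boundary_construction(self):
        rc = critical_r(24, 0.05)
        assert classify_effects(rc + 1e-6, 24)[0] == "significant"
        assert classify_effects(rc - 1e-6, 24)[0] == "marginal"

    def test_marginal_band(self):
        # find r with p ~ 0.07 one-sided at n=24
        from scipy.optimize import brentq

        r = brentq(lambda x: r_p_value(x, 24, "one_sided_positive") - 0.07, 0.0, 0.99)
        assert classify_effects(r, 24)[0] == "marginal"

    def test_consistency_with_critical_value(self):
        """significant  <=>  r > critical_r(n, alpha_sig)."""
        rng = np.random.default_rng(3)
        r = rng.uniform(-0.9, 0.9, 500)
        n = rng.integers(5, 120, 500)
        cats = classify_effects(r, n)
        assert np.array_equal(cats == "significant", r > critical_r(n, 0.05))


class TestPredictivenessScore:
    @pytest.mark.parametrize(
        "rs, expected",
        [
            ([0.8] + [0.01] * 9, 1.0),  # 1 significant among 10 -> max score
            ([0.01, 0.02, -0.3], 0.0),  # all nonsignificant
            ([0.30, 0.01], 0.5),  # marginal only (r=0.30 at n=24)
        ],
    )
    def test_score_rules(self, rs, expected):
        score = predictiveness_score(_group(rs, n=24), POLICY)
        assert score.score == expected
        assert score.n_significant + score.n_marginal + score.n_nonsignificant == score.k == len(rs)

    def test_empty_group_rejected(self):
        with pytest.raises(EffectTableError):
            predictiveness_score(_group([]).iloc[0:0], POLICY)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(st.floats(-0.9, 0.9), min_size=1, max_size=8),
        st.floats(-0.9, 0.9),
    )
    def test_adding_an_effect_never_lowers_the_score(self, rs, extra):
        before = predictiveness_score(_group(rs, n=24), POLICY).score
        after = predictiveness_score(_group(rs + [extra], n=24), POLICY).score
        assert after >= before

    def test_score_table_groups_by_study(self, small_table):
        tab = score_table(small_table, POLICY)
        assert len(tab) == 4
        assert set(tab["score"]) <= {0.0, 0.5, 1.0}


class TestFilteredMeans:
    def test_arithmetic_on_classified_group(self):
        g = _group([0.60, 0.50, 0.10], n=30)
        assert filtered_mean(g, POLICY) == pytest.approx(0.55)

    def test_absent_marker_when_nothing_qualifies(self):
        assert np.isnan(filtered_mean(_group([0.05, -0.2], n=30), POLICY))

    def test_guaranteed_minimum_floor(self):
        """Every present filtered mean >= smallest marginal critical value."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            k = rng.integers(1, 8)
            n = int(rng.integers(5, 80))
            g = _group(rng.uniform(-0.9, 0.9, k).tolist(), n=n)
            fm = filtered_mean(g, POLICY)
            if np.isfinite(fm):
                assert fm >= critical_r(n, POLICY.alpha_marginal) - 1e-12

    def test_measure_level_average_unit_is_papers(self):
        # two papers with filtered means 0.5 and 0.6 but unequal effect counts:
        # effect-pooled mean would differ from the paper-level mean
        df = pd.concat(
            [
                _group([0.5, 0.5, 0.5], n=40, paper="P1"),
                _group([0.6], n=40, paper="P2"),
            ],
            ignore_index=True,
        )
        res = filter_dataset(df, POLICY)
        assert measure_level_filtered_mean(res, "SAGAT") == pytest.approx(0.55)
        pooled = res.retained["r"].mean()
        assert pooled != pytest.approx(0.55)

    def test_single_paper_measure(self):
        res = filter_dataset(_group([0.6], n=40), POLICY)
        assert measure_level_filtered_mean(res, "SAGAT") == pytest.approx(0.6)
        assert np.isnan(measure_level_filtered_mean(res, "SPAM"))


class TestFilterDataset:
    def test_partition_conserves_counts(self, literature):
        res = filter_dataset(literature, POLICY)
        assert res.n_retained + res.n_discarded == len(literature)
        merged = pd.concat([res.retained, res.discarded])
        assert len(merged) == len(literature)
        assert sorted(merged["r"]) == pytest.approx(sorted(literature["r"]))

    def test_all_discarded_when_nothing_qualifies(self):
        res = filter_dataset(_group([0.01, -0.5, 0.02], n=24), POLICY)
        assert res.n_retained == 0
        assert res.proportion_discarded == 1.0

    def test_overall_means_exposed_under_both_units(self, literature):
        res = filter_dataset(literature, POLICY)
        means = measure_level_filtered_means(res)
        assert "overall" in means and "overall_by_measure" in means
        assert means.drop(["overall", "overall_by_measure"]).between(-1, 1).all()


class TestBoundaryCurve:
    def test_shape_and_columns(self):
        tab = boundary_curve(5, 200)
        assert list(tab.columns) == ["n", "critical_r_sig", "critical_r_marginal"]
        assert len(tab) == 196
        assert (tab["critical_r_marginal"] < tab["critical_r_sig"]).all()
        assert tab["critical_r_sig"].is_monotonic_decreasing

    def test_domain(self):
        with pytest.raises(EffectTableError):
            boundary_curve(3, 10)
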