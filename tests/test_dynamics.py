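"""Cross-session dynamics: changes, similarity, transitions, reoccurrence,
novel-high recruitment, and the two-sample test oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from catrack import dynamics as dyn
from catrack.simulate import appps1_like_population, simulate_rate_table, wt_like_population


def table_from_rates(rates_by_session, fov=0):
    """Longitudinal table from {session: [rates...]} with matched neuron IDs."""
    from catrack.detect import classify_activity

    rows = []
    for sid, rates in rates_by_session.items():
        for nid, r in enumerate(rates):
            rows.append(
                {
                    "neuron_id": nid,
                    "session_id": sid,
                    "rate": r,
                    "auc": np.nan,
                    "category": classify_activity(r),
                    "fov_id": fov,
                    "cohort": "",
                }
            )
    return pd.DataFrame(rows)


class TestActivityChange:
    def test_identical_sessions_zero(self):
        t = table_from_rates({0: [1.0, 2.0, 3.0], 1: [1.0, 2.0, 3.0]})
        assert (dyn.activity_change(t, 0, 1) == 0).all()

    def test_arithmetic(self):
        t = table_from_rates({0: [1.0], 1: [3.5]})
        assert dyn.activity_change(t, 0, 1).iloc[0] == pytest.approx(2.5)

    def test_drift_mostly_within_two_transients(self):
        # truncated-normal drift of sd 1: >= 75% of |Δ| <= 2 transients/min
        pop = appps1_like_population(1000)
        t = simulate_rate_table(pop, n_sessions=2, drift_sd=1.0, seed=3)
        delta = dyn.activity_change(t, 0, 1)
        assert (delta.abs() <= 2.0).mean() >= 0.75


class TestSimilarity:
    def test_identity_is_one(self):
        x = np.array([0.5, 1.0, 3.0, 4.0])
        assert dyn.similarity_index(x, x) == pytest.approx(1.0)

    def test_affine_invariance(self):
        x = np.array([0.5, 1.0, 3.0, 4.0])
        assert dyn.similarity_index(x, 2.5 * x + 1.0) == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        x = np.array([1.0, 1.0, 1.0, 1.0])
        assert np.isnan(dyn.similarity_index(x, np.array([1.0, 2.0, 3.0, 4.0])))

    def test_shuffle_null_centered_on_zero(self, rng):
        rates = rng.lognormal(0, 1, 50)
        t = table_from_rates({0: rates, 1: rates * rng.lognormal(0, 0.3, 50)})
        null = dyn.shuffle_null_similarity(t, 0, 1, n_shuffles=100, seed=0)
        assert -0.05 <= np.nanmean(null) <= 0.05

    def test_shuffle_is_seeded(self):
        rates = np.arange(1.0, 21.0)
        t = table_from_rates({0: rates, 1: rates[::-1]})
        a = dyn.shuffle_null_similarity(t, 0, 1, n_shuffles=20, seed=9)
        b = dyn.shuffle_null_similarity(t, 0, 1, n_shuffles=20, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_exhaustive_mode_enumerates_permutations(self):
        t = table_from_rates({0: [1.0, 2.0], 1: [1.0, 2.0]})
        vals = dyn.shuffle_null_similarity(t, 0, 1, exhaustive=True)
        assert len(vals) == 2  # the two permutations of two neurons
        np.testing.assert_allclose(sorted(vals), [-1.0, 1.0])


class TestTransitions:
    def test_identity_matrix_when_no_change(self):
        t = table_from_rates({0: [0.1, 1.0, 5.0], 1: [0.15, 2.0, 6.0]})
        res = dyn.transition_matrix(t, 0, 1)
        assert res.fractions.loc["rare", "rare"] == 1.0
        assert res.fractions.loc["intermediate", "intermediate"] == 1.0
        assert res.fractions.loc["high", "high"] == 1.0

    def test_recruitment_fraction_counted(self):
        # 10 intermediate at s0, one becomes high
        rates0 = [1.0] * 10
        rates1 = [1.0] * 9 + [5.0]
        res = dyn.transition_matrix(table_from_rates({0: rates0, 1: rates1}), 0, 1)
        assert res.recruitment_rate == pytest.approx(0.10)

    def test_counts_conserved(self, rng):
        rates0 = rng.lognormal(0, 1.5, 200)
        rates1 = np.clip(rates0 + rng.normal(0, 1, 200), 0, None)
        t = table_from_rates({0: rates0, 1: rates1})
        res = dyn.transition_matrix(t, 0, 1)
        assert res.counts.to_numpy().sum() == 200
        from catrack.detect import classify_activity

        for cat in ("rare", "intermediate", "high"):
            n_cat = sum(classify_activity(r) == cat for r in rates0)
            assert res.counts.loc[cat].sum() == n_cat

    def test_app_like_drift_recruits_more_than_wt(self):
        app = simulate_rate_table(
            appps1_like_population(1000),
            drift_mean={"intermediate": 0.3},
            drift_sd=1.0,
            seed=21,
        )
        wt = simulate_rate_table(wt_like_population(1000), drift_sd=1.0, seed=22)
        r_app = dyn.transition_matrix(app, 0, 1).recruitment_rate
        r_wt = dyn.transition_matrix(wt, 0, 1).recruitment_rate
        assert r_app > r_wt


class TestReoccurrence:
    def test_all_persist(self):
        t = table_from_rates({0: [5.0, 6.0, 7.0], 1: [5.5, 6.5, 8.0]})
        assert dyn.reoccurrence_rate(t, "high", 0, 1) == 1.0

    def test_three_of_five(self):
        t = table_from_rates({0: [5.0] * 5, 1: [5.0, 5.0, 5.0, 1.0, 1.0]})
        assert dyn.reoccurrence_rate(t, "high", 0, 1) == pytest.approx(0.6)

    def test_matches_transition_diagonal(self, rng):
        rates0 = rng.lognormal(0.5, 1.2, 300)
        rates1 = np.clip(rates0 + rng.normal(0, 1, 300), 0, None)
        t = table_from_rates({0: rates0, 1: rates1})
        res = dyn.transition_matrix(t, 0, 1)
        for cat in ("rare", "intermediate", "high"):
            if res.counts.loc[cat].sum():
                assert dyn.reoccurrence_rate(t, cat, 0, 1) == pytest.approx(
                    res.fractions.loc[cat, cat]
                )

    def test_rare_reoccurrence_near_zero_under_drift(self):
        # category width 0.25 vs drift sd 1.0: a two-step random walk leaves
        # only the small central mass (~2 x 0.25 x N(0, sqrt(2)) density)
        # inside the rare band
        pop = appps1_like_population(2000)
        t = simulate_rate_table(pop, n_sessions=3, drift_sd=1.0, seed=5)
        assert dyn.reoccurrence_rate(t, "rare", 0, 2) <= 0.2

    def test_empty_category_rejected(self):
        t = table_from_rates({0: [1.0, 2.0], 1: [1.0, 2.0]})
        with pytest.raises(ValueError):
            dyn.reoccurrence_rate(t, "high", 0, 1)


class TestNovelHigh:
    def test_no_new_high_flagged(self):
        t = table_from_rates({0: [1.0, 5.0], 1: [1.0, 5.0]})
        res = dyn.novel_high_analysis(t, 0, 1)
        assert res.n_new_high == 0
        assert np.isnan(res.frac_from_intermediate)

    def test_source_fractions_counted(self):
        # 4 new high cells, 3 formerly intermediate, 1 formerly rare
        rates0 = [1.0, 1.0, 1.0, 0.1, 5.0]
        rates1 = [5.0, 5.0, 5.0, 5.0, 5.0]
        res = dyn.novel_high_analysis(table_from_rates({0: rates0, 1: rates1}), 0, 1)
        assert res.n_new_high == 4
        assert res.frac_from_intermediate == pytest.approx(0.75)
        assert res.frac_from_rare == pytest.approx(0.25)

    def test_gain_positive_and_ci_ordered(self):
        rates0 = [3.0, 3.5, 2.0, 1.0]
        rates1 = [5.0, 6.0, 4.5, 1.0]
        res = dyn.novel_high_analysis(table_from_rates({0: rates0, 1: rates1}), 0, 1, seed=1)
        assert res.mean_gain > 0
        assert res.ci_low <= res.mean_gain <= res.ci_high

    def test_bootstrap_seeded(self):
        t = table_from_rates({0: [3.0, 2.0, 1.0], 1: [5.0, 6.0, 1.0]})
        a = dyn.novel_high_analysis(t, 0, 1, seed=4)
        b = dyn.novel_high_analysis(t, 0, 1, seed=4)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


def brute_force_ks(a, b):
    """sup |ECDF_a - ECDF_b| by scanning every sample point."""
    pts = np.concatenate([a, b])
    return max(
        abs((a <= x).mean() - (b <= x).mean()) for x in pts
    )


def brute_force_u(a, b):
    """Mann-Whitney U of sample a by direct pair counting."""
    return sum((x > y) + 0.5 * (x == y) for x in a for y in b)


class TestTwoSampleOracles:
    def test_ks_trivial_cases(self):
        d, _ = dyn.compare_change_distributions([0.0, 0.0], [1.0, 1.0])
        assert d == 1.0
        d, _ = dyn.compare_change_distributions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0

    def test_ks_matches_ecdf_scan(self, rng):
        d, _ = dyn.compare_change_distributions([1.0, 2.0, 3.0], [1.5, 2.5])
        assert d == pytest.approx(brute_force_ks(np.array([1.0, 2, 3]), np.array([1.5, 2.5])))
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 10))
            b = rng.normal(size=rng.integers(2, 10))
            d, _ = dyn.compare_change_distributions(a, b)
            assert d == pytest.approx(brute_force_ks(a, b), abs=1e-12)

    def test_ks_exact_p_by_enumeration(self):
        # tiny samples: exact p = fraction of label assignments with D >= observed
        a = np.array([0.3, 1.1, 2.2])
        b = np.array([0.9, 1.7, 2.5])
        d_obs, p = dyn.compare_change_distributions(a, b)
        pooled = np.concatenate([a, b])
        n = len(a)
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n):
            aa = pooled[list(idx)]
            bb = np.delete(pooled, list(idx))
            total += 1
            if brute_force_ks(aa, bb) >= d_obs - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-9)

    def test_u_matches_pair_counting(self, rng):
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 10))
            b = rng.normal(size=rng.integers(2, 10))
            u, _ = dyn.mann_whitney(a, b)
            assert u == pytest.approx(brute_force_u(a, b))

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            dyn.compare_change_distributions([], [1.0])
        with pytest.raises(ValueError):
            dyn.mann_whitney([1.0], [])


class TestNoDriftLimit:
    def test_median_change_vanishes_without_drift(self):
        pop = wt_like_population(500)
        t = simulate_rate_table(pop, n_sessions=2, drift_mean=0.0, drift_sd=0.0, seed=8)
        delta = dyn.activity_change(t, 0, 1)
        assert np.median(np.abs(delta)) == 0.0
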