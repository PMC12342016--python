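"""Hypergeometric enrichment, BH adjustment, and attribute-association tests."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import paretoscope as ps
from paretoscope.enrichment import mannwhitney_p
from paretoscope.io import GeneSetCollection
from paretoscope.simplex import SimplexFit


def hypergeom_tail_oracle(N, K, n, x):
    """P(X >= x) by direct pmf summation."""
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(x, min(K, n) + 1)) / comb(N, n)


def _gmt(**sets):
    return GeneSetCollection(sets={k: ("", v) for k, v in sets.items()})


def _fit_with_weights(w):
    w = np.asarray(w, dtype=float)
    return SimplexFit(k=w.shape[1], archetypes_pc=np.eye(w.shape[1])[:, :-1],
                      vertex_sample_indices=None, weights=w, esv=1.0)


class TestHypergeometricEnrichment:
    def test_textbook_tail_probability(self):
        universe = [f"g{i}" for i in range(20)]
        res = ps.hypergeometric_enrichment(
            universe[:5], _gmt(S=universe[1:6]), universe)
        # overlap 4 of K=5 in a list of 5 from N=20: p = 76/15504
        assert res[0].overlap == 4
        assert res[0].p_raw == pytest.approx(76 / 15504, rel=1e-12)

    def test_empty_set_intersection_gives_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = ps.hypergeometric_enrichment(universe[:3], _gmt(S=["zz"]), universe)
        assert res[0].p_raw == 1.0

    def test_list_equals_universe_certainty(self):
        universe = [f"g{i}" for i in range(12)]
        res = ps.hypergeometric_enrichment(universe, _gmt(S=universe[:4]), universe)
        assert res[0].overlap == 4
        assert res[0].p_raw == pytest.approx(1.0)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError, match="universe"):
            ps.hypergeometric_enrichment([], _gmt(S=["a"]), [])

    def test_matches_summation_oracle_on_grid(self):
        universe = [f"g{i}" for i in range(60)]
        rng = np.random.default_rng(0)
        for _ in range(40):
            N = int(rng.integers(10, 61))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            uni = universe[:N]
            members = uni[:K]
            glist = list(rng.choice(uni, size=n, replace=False))
            res = ps.hypergeometric_enrichment(glist, _gmt(S=members), uni)
            x = len(set(glist) & set(members))
            assert res[0].p_raw == pytest.approx(
                hypergeom_tail_oracle(N, K, n, x), abs=1e-12)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert ps.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_textbook_step_up(self):
        np.testing.assert_allclose(ps.bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(ps.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_invalid_p_rejected(self):
        for bad in ([0.0, 0.5], [1.2], [-0.1]):
            with pytest.raises(ValueError):
                ps.bh_adjust(bad)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=30))
    def test_matches_step_up_oracle(self, pvals):
        p = np.array(pvals)
        m = len(p)
        order = np.argsort(p)
        q_oracle = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            q_oracle[i] = running
        np.testing.assert_allclose(ps.bh_adjust(p), q_oracle, rtol=1e-10)


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        # bin {1,2,3} vs rest {4,5,6}: the two extreme assignments of C(6,3)=20
        assert mannwhitney_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_give_one(self):
        assert mannwhitney_p([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.integers(0, 4, size=int(rng.integers(3, 8))).astype(float)
            y = rng.integers(0, 4, size=int(rng.integers(3, 8))).astype(float)
            # oracle: count pair wins/ties per assignment directly
            pooled = np.concatenate([x, y])
            n1 = len(x)

            def u_stat(idx):
                a = pooled[list(idx)]
                b = np.delete(pooled, list(idx))
                return sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)

            mu = n1 * (len(pooled) - n1) / 2
            obs = abs(u_stat(range(n1)) - mu)
            combos = list(itertools.combinations(range(len(pooled)), n1))
            p_oracle = np.mean([abs(u_stat(c) - mu) >= obs - 1e-9 for c in combos])
            assert mannwhitney_p(x, y) == pytest.approx(p_oracle, abs=1e-12)

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.8, 1, 40)
        from scipy import stats

        expected = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert mannwhitney_p(x, y) == pytest.approx(float(expected))


class TestBinning:
    def test_bin_fraction_one_takes_everyone(self):
        fit = _fit_with_weights(np.eye(3)[[0, 1, 2, 0]])
        ids = ["a", "b", "c", "d"]
        b, r = ps.bin_samples_by_archetype(fit, 0, ids, bin_fraction=1.0)
        assert b == sorted(ids) and r == []

    def test_one_hot_weights_bin_matches_assignment(self):
        w = np.array([[1, 0], [1, 0], [0, 1], [0, 1.0]])
        fit = _fit_with_weights(w)
        b, _ = ps.bin_samples_by_archetype(fit, 0, ["a", "b", "c", "d"], bin_fraction=0.5)
        assert b == ["a", "b"]

    def test_invariant_to_sample_order(self, tetra_fit, tetra_truth):
        ids = tetra_truth.expression.sample_ids
        b1, _ = ps.bin_samples_by_archetype(tetra_fit, 1, ids, 0.1)
        perm = np.random.default_rng(3).permutation(len(ids))
        fit2 = SimplexFit(k=4, archetypes_pc=tetra_fit.archetypes_pc,
                          vertex_sample_indices=None,
                          weights=tetra_fit.weights[perm], esv=tetra_fit.esv)
        b2, _ = ps.bin_samples_by_archetype(fit2, 1, [ids[i] for i in perm], 0.1)
        assert b1 == b2


class TestAttributeTests:
    def test_all_one_category_bin_tail_probability(self):
        # 40 samples, prevalence 50%, bin of 10 all category "c":
        # p = C(20,10)/C(40,10) by the pmf oracle
        ids = [f"s{i:02d}" for i in range(40)]
        w = np.zeros((40, 2))
        w[:10, 0] = 1.0
        w[10:, 1] = 1.0
        labels = {s: ("c" if i < 10 or i >= 30 else "d") for i, s in enumerate(ids)}
        fit = _fit_with_weights(w)
        res = ps.attribute_discrete(fit, labels, 0, ids, bin_fraction=0.25)
        pc = next(r for r in res if r.category == "c")
        assert pc.p_raw == pytest.approx(hypergeom_tail_oracle(40, 20, 10, 10), rel=1e-10)
        assert pc.effect == pytest.approx(2.0)

    def test_discrete_calibration_under_random_bins(self):
        """Random bins: hypergeometric p rejects ~ alpha of the time."""
        rng = np.random.default_rng(4)
        n, alpha = 60, 0.05
        ids = [f"s{i}" for i in range(n)]
        labels = {s: ("x" if i % 2 else "y") for i, s in enumerate(ids)}
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            w = rng.random((n, 2))
            w /= w.sum(axis=1, keepdims=True)
            res = ps.attribute_discrete(_fit_with_weights(w), labels, 0, ids, 0.2)
            rejections += min(r.p_raw for r in res) <= alpha / 2  # Sidak-ish for 2 cats
        rate = rejections / n_sim
        assert rate <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_sim)

    def test_planted_label_gradient_found(self, tetra_truth, tetra_fit):
        table = ps.AttributeTable(
            sample_ids=tetra_truth.expression.sample_ids,
            discrete={"label": tetra_truth.discrete_labels},
            continuous={"covariate": tetra_truth.continuous_covariate},
        )
        res = ps.test_attributes(tetra_fit, table, tetra_truth.expression.sample_ids, 0.1)
        disc = [r for r in res if r.kind == "discrete" and r.category == "A"]
        best = min(disc, key=lambda r: r.q_bh)
        assert best.q_bh < 0.01 and best.effect > 1.5
        cont = [r for r in res if r.kind == "continuous"]
        best_c = min(cont, key=lambda r: r.q_bh)
        # the covariate grows with weight on the planted archetype, so the
        # strongest association has a positive median difference
        assert best_c.archetype_index == best.archetype_index
        assert best_c.effect > 0 and best_c.q_bh < 0.01

    def test_missing_values_dropped_testwise(self, tetra_fit, tetra_truth):
        ids = tetra_truth.expression.sample_ids
        cov = {s: v for s, v in tetra_truth.continuous_covariate.items() if s not in ids[:100]}
        res = ps.attribute_continuous(tetra_fit, cov, 0, ids, 0.1)
        assert res.n_bin + res.n_rest == len(cov)
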