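"""Sibling contrasts, rank tests, and clade blocking."""

import itertools

import numpy as np
import pytest
from scipy import stats

from sparsecomp import (
    bootstrap_mean_test,
    clade_normalize,
    extract_contrasts,
    kruskal_wallis,
    make_balanced_tree,
    propagate_states,
    read_newick,
    srh_test,
    wilcoxon_signed_rank,
)


class TestPropagateStates:
    def test_unanimous_positive_cherry(self):
        tree = read_newick("(A:1,B:1);")
        x, y = propagate_states(tree, {"A": 1, "B": 1}, {"A": 1.0, "B": 2.0})
        assert x[tree.root] == 1

    def test_mixed_cherry_is_negative_with_mean_response(self):
        tree = read_newick("(A:1,B:1);")
        x, y = propagate_states(tree, {"A": 1, "B": 0}, {"A": 4.0, "B": 2.0})
        assert x[tree.root] == 0
        assert y[tree.root] == 3.0

    def test_constant_response_propagates_unchanged(self):
        tree = make_balanced_tree(4)
        tips = {lab: 7.0 for lab in tree.tip_labels()}
        ones = {lab: 1 for lab in tree.tip_labels()}
        _, y = propagate_states(tree, ones, tips)
        assert all(v == 7.0 for v in y.values())

    def test_missing_tip_rejected(self):
        tree = read_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            propagate_states(tree, {"A": 1}, {"A": 1.0, "B": 2.0})


class TestExtractContrasts:
    def test_no_diversity_gives_empty_list(self):
        tree = make_balanced_tree(3)
        zeros = {lab: 0 for lab in tree.tip_labels()}
        ys = {lab: float(i) for i, lab in enumerate(tree.tip_labels())}
        assert extract_contrasts(tree, propagate_states(tree, zeros, ys)) == []

    def test_hand_computed_root_contrast(self, four_tip_tree):
        labels = propagate_states(
            four_tip_tree,
            {"A": 1, "B": 1, "C": 0, "D": 0},
            {"A": 1.0, "B": 2.0, "C": 5.0, "D": 7.0},
        )
        contrasts = extract_contrasts(four_tip_tree, labels)
        assert len(contrasts) == 1
        c = contrasts[0]
        assert c.y_plus == 1.5 and c.y_minus == 6.0 and c.diff == -4.5

    def test_trifurcation_averages_within_class(self):
        tree = read_newick("(A:1,B:1,C:1);")
        labels = propagate_states(
            tree, {"A": 1, "B": 1, "C": 0}, {"A": 2.0, "B": 4.0, "C": 9.0}
        )
        contrasts = extract_contrasts(tree, labels)
        assert len(contrasts) == 1
        assert contrasts[0].y_plus == 3.0
        assert contrasts[0].y_minus == 9.0
        assert contrasts[0].diff == -6.0

    def test_contrast_nodes_are_disjoint(self):
        # one contrast per internal node: parents never repeat
        tree = make_balanced_tree(4)
        rng = np.random.default_rng(0)
        x = {lab: int(rng.random() < 0.5) for lab in tree.tip_labels()}
        y = {lab: float(rng.normal()) for lab in tree.tip_labels()}
        contrasts = extract_contrasts(tree, propagate_states(tree, x, y))
        parents = [c.parent_node for c in contrasts]
        assert len(parents) == len(set(parents))


def exact_signed_rank_enumeration(diffs):
    """Brute force: all 2^n sign assignments of the |diff| ranks."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    p_le = np.mean(ws <= w_obs)
    p_ge = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_perfect_symmetry_gives_p_one(self):
        assert wilcoxon_signed_rank([1.0, -1.0]).p_value == 1.0

    def test_all_positive_n6_exact(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        assert res.p_value == pytest.approx(2 / 64)

    def test_sign_flip_symmetry(self):
        diffs = [0.5, -1.2, 2.0, 3.3, -0.1]
        assert wilcoxon_signed_rank(diffs).p_value == pytest.approx(
            wilcoxon_signed_rank([-d for d in diffs]).p_value
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        diffs = np.round(rng.normal(0.3, 1.0, n), 1)  # rounding forces ties
        diffs = diffs[diffs != 0]
        if len(diffs) == 0:
            return
        res = wilcoxon_signed_rank(diffs)
        assert res.p_value == pytest.approx(
            exact_signed_rank_enumeration(diffs), abs=1e-12
        )

    def test_all_zero_diffs_flagged_not_raised(self):
        with pytest.warns(UserWarning):
            res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.p_value == 1.0 and res.all_zero

    def test_large_sample_approximation_is_close_to_scipy(self):
        rng = np.random.default_rng(3)
        diffs = rng.normal(0.3, 1.0, 40)
        res = wilcoxon_signed_rank(diffs)
        ref = stats.wilcoxon(diffs, alternative="two-sided", correction=True)
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.05)


class TestBootstrap:
    def test_identical_positive_diffs_reach_floor(self):
        res = bootstrap_mean_test([3.0] * 10, B=1000, seed=0)
        assert res.p_value <= 2 / 1000

    def test_symmetric_diffs_give_large_p(self):
        rng = np.random.default_rng(1)
        diffs = np.concatenate([rng.normal(0, 1, 100), -rng.normal(0, 1, 100)])
        res = bootstrap_mean_test(diffs, B=5000, seed=2)
        assert res.p_value > 0.85

    def test_seeded_determinism(self):
        diffs = [1.0, -0.5, 2.0, 0.3, -1.1]
        a = bootstrap_mean_test(diffs, B=500, seed=7)
        b = bootstrap_mean_test(diffs, B=500, seed=7)
        assert a.p_value == b.p_value

    def test_too_few_diffs_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_mean_test([1.0], B=1000, seed=0)


def rank_anova_oracle(y, group, block):
    """Independent two-way ranks ANOVA: H = SS_effect / (SS_total/(N-1))."""
    ranks = stats.rankdata(y)
    grand = ranks.mean()
    ss_total = np.sum((ranks - grand) ** 2)

    def ss_for(f):
        return sum(
            (f == lev).sum() * (ranks[f == lev].mean() - grand) ** 2
            for lev in np.unique(f)
        )

    return ss_for(np.asarray(group)) / (ss_total / (len(y) - 1))


class TestSRH:
    def test_single_block_reduces_to_kruskal_wallis(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=30)
        g = rng.integers(0, 3, 30)
        res = srh_test(y, g, np.zeros(30, dtype=int))
        h, p = stats.kruskal(*[y[g == k] for k in range(3)])
        assert res.statistic == pytest.approx(h, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_constant_response(self):
        res = srh_test([5.0] * 12, [0, 1] * 6, [0, 0, 1, 1] * 3)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_balanced_layout_matches_rank_anova_oracle(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=24)
        g = np.repeat([0, 1], 12)
        b = np.tile(np.repeat([0, 1], 6), 2)
        res = srh_test(y, g, b)
        assert res.statistic == pytest.approx(rank_anova_oracle(y, g, b), abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=30)
        g = rng.integers(0, 2, 30)
        b = rng.integers(0, 3, 30)
        a = srh_test(y, g, b)
        t = srh_test(np.exp(y), g, b)
        assert a.statistic == pytest.approx(t.statistic, abs=1e-10)

    def test_single_group_directs_to_kruskal_wallis(self):
        with pytest.raises(ValueError, match="kruskal"):
            srh_test([1.0, 2.0, 3.0], [0, 0, 0], [0, 1, 2])

    def test_block_and_interaction_components_present(self):
        rng = np.random.default_rng(7)
        res = srh_test(rng.normal(size=40), rng.integers(0, 2, 40),
                       rng.integers(0, 2, 40))
        assert set(res.components) == {"block", "interaction"}


class TestKruskalWallis:
    def test_two_groups_matches_enumeration(self):
        # exact permutation reference for n = 4
        y = np.array([1.0, 2.0, 3.0, 4.0])
        g = np.array([0, 0, 1, 1])
        res = kruskal_wallis(y, g)
        h_ref, _ = stats.kruskal(y[g == 0], y[g == 1])
        assert res.statistic == pytest.approx(h_ref)
        # permutation p: fraction of group assignments with H >= observed
        hs = []
        for idx in itertools.combinations(range(4), 2):
            grp = np.zeros(4, dtype=int)
            grp[list(idx)] = 1
            hs.append(stats.kruskal(y[grp == 0], y[grp == 1])[0])
        assert res.statistic == pytest.approx(max(hs))

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(8)
        rej = 0
        n_sims = 1000
        for _ in range(n_sims):
            y = rng.normal(size=40)
            g = np.repeat([0, 1], 20)
            rej += kruskal_wallis(y, g).p_value < 0.05
        assert 0.03 <= rej / n_sims <= 0.07

    def test_constant_response_gives_zero_h(self):
        res = kruskal_wallis([2.0] * 10, [0, 1] * 5)
        assert res.statistic == 0.0

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], [0, 0])


class TestCladeNormalize:
    def test_single_clade_centers(self):
        y = {"a": 1.0, "b": 2.0, "c": 3.0}
        out = clade_normalize(y, {k: 0 for k in y})
        assert sum(out.values()) == pytest.approx(0.0)
        assert out["a"] == pytest.approx(-1.0)

    def test_two_clades_both_centered(self):
        y = {"a": 9.0, "b": 11.0, "c": 49.0, "d": 51.0}
        clades = {"a": 0, "b": 0, "c": 1, "d": 1}
        out = clade_normalize(y, clades)
        assert out["a"] == -1.0 and out["b"] == 1.0
        assert out["c"] == -1.0 and out["d"] == 1.0

    def test_per_clade_constant_shift_invariance_of_pgls_slope(self):
        # normalize-then-fit is invariant to adding a per-clade offset
        from sparsecomp import CovarianceSpec, assign_clades, fit_pgls

        tree = make_balanced_tree(4)
        labels = tree.tip_labels()
        rng = np.random.default_rng(9)
        x = dict(zip(labels, rng.integers(0, 2, 16).astype(float)))
        y = dict(zip(labels, rng.normal(10, 2, 16)))
        clades = assign_clades(tree)
        shifted = {lab: y[lab] + 40.0 * clades[lab] for lab in labels}
        a = fit_pgls(x, clade_normalize(y, clades), tree, CovarianceSpec("brownian"))
        b = fit_pgls(x, clade_normalize(shifted, clades), tree,
                     CovarianceSpec("brownian"))
        assert a.slope == pytest.approx(b.slope, abs=1e-10)
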