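"""Tree container, Newick round-trips, simulation, and covariance structures."""

import numpy as np
import pytest

from sparsecomp import (
    CovarianceSpec,
    NewickParseError,
    assign_clades,
    birth_death_tip_count,
    covariance_matrix,
    extract_subtree,
    make_balanced_tree,
    mrca,
    patristic_distances,
    prune_to_tips,
    read_newick,
    simulate_birth_death_tree,
    write_newick,
)

from conftest import brute_force_brownian, random_tree


class TestBalancedTree:
    def test_degenerate_single_tip(self):
        tree = make_balanced_tree(0)
        assert tree.n_tips == 1

    def test_256_leaves_at_depth_8(self):
        tree = make_balanced_tree(8)
        assert tree.n_tips == 256

    def test_root_to_tip_paths_equal_depth(self):
        tree = make_balanced_tree(3, branch_length=1.0)
        depths = tree.node_depths()
        assert all(depths[v] == 3.0 for v in tree.tips())

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            make_balanced_tree(-1)


class TestBirthDeath:
    def test_pure_birth_is_ultrametric(self):
        tree = simulate_birth_death_tree(16, birth=1.0, death_nu=0.0, seed=3)
        assert tree.n_tips == 16
        depths = tree.node_depths()
        tip_depths = [depths[v] for v in tree.tips()]
        assert np.allclose(tip_depths, tip_depths[0])

    def test_seeded_determinism(self):
        a = simulate_birth_death_tree(64, birth=1.0, death_nu=0.5, seed=1)
        b = simulate_birth_death_tree(64, birth=1.0, death_nu=0.5, seed=1)
        assert write_newick(a) == write_newick(b)

    def test_death_above_birth_rejected(self):
        with pytest.raises(ValueError):
            simulate_birth_death_tree(16, birth=1.0, death_nu=1.5, seed=0)

    def test_mean_tip_count_matches_analytic_growth(self):
        # E[N(T)] = 2 exp((b - nu) T) starting from two root lineages
        b, nu, T = 1.0, 0.4, 2.0
        counts = [birth_death_tip_count(b, nu, T, seed=s) for s in range(200)]
        expected = 2 * np.exp((b - nu) * T)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 4 * se


class TestNewick:
    def test_two_tip_parse(self):
        tree = read_newick("(A:1,B:1):0;")
        assert tree.n_tips == 2
        assert sorted(tree.tip_labels()) == ["A", "B"]
        for v in tree.tips():
            assert tree.branch_length(v) == 1.0

    def test_absent_lengths_stay_absent(self):
        tree = read_newick("((A,B),C);")
        assert all(tree.branch_length(v) is None for v in tree.tips())

    def test_duplicate_labels_rejected(self):
        with pytest.raises(NewickParseError):
            read_newick("(A:1,A:1);")

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(NewickParseError):
            read_newick("((A:1,B:1):1;")

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_preserves_topology_and_lengths(self, seed):
        tree = random_tree(seed, n_tips=50, death=0.3)
        back = read_newick(write_newick(tree))
        assert sorted(back.tip_labels()) == sorted(tree.tip_labels())
        V1 = covariance_matrix(tree, CovarianceSpec("brownian"))
        V2 = covariance_matrix(back, CovarianceSpec("brownian"))
        common = sorted(tree.tip_labels())
        np.testing.assert_allclose(
            V1.loc[common, common].to_numpy(),
            V2.loc[common, common].to_numpy(),
            atol=1e-6,
        )


class TestCovariance:
    def test_brownian_hand_example(self, cherry_tree):
        V = covariance_matrix(cherry_tree, CovarianceSpec("brownian"))
        assert V.loc["A", "A"] == 2 and V.loc["B", "B"] == 2
        assert V.loc["A", "B"] == 1
        assert V.loc["C", "C"] == 2
        assert V.loc["A", "C"] == 0 and V.loc["B", "C"] == 0

    def test_lambda_zero_is_diagonal(self, cherry_tree):
        V = covariance_matrix(cherry_tree, CovarianceSpec("pagel_lambda", 0.0))
        np.testing.assert_allclose(V.to_numpy(), np.diag([2.0, 2.0, 2.0]))

    def test_lambda_one_equals_brownian(self):
        tree = random_tree(7, n_tips=15)
        V1 = covariance_matrix(tree, CovarianceSpec("pagel_lambda", 1.0))
        V0 = covariance_matrix(tree, CovarianceSpec("brownian"))
        np.testing.assert_allclose(V1.to_numpy(), V0.to_numpy())

    @pytest.mark.parametrize("seed", range(8))
    def test_brownian_matches_path_sum_oracle(self, seed):
        tree = random_tree(seed, n_tips=20, death=0.2)
        V = covariance_matrix(tree, CovarianceSpec("brownian")).to_numpy()
        np.testing.assert_allclose(V, brute_force_brownian(tree), atol=1e-12)

    @pytest.mark.parametrize(
        "spec",
        [
            CovarianceSpec("identity"),
            CovarianceSpec("brownian"),
            CovarianceSpec("pagel_lambda", 0.5),
            CovarianceSpec("martins_hansen", 0.3),
            CovarianceSpec("grafen", 1.0),
        ],
        ids=lambda s: s.model,
    )
    def test_symmetric_positive_semidefinite(self, spec):
        tree = random_tree(11, n_tips=18)
        V = covariance_matrix(tree, spec).to_numpy()
        np.testing.assert_allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() >= -1e-9

    def test_martins_hansen_large_alpha_approaches_identity(self):
        tree = make_balanced_tree(3)  # min distance 2, max 6
        alpha = 50.0 / patristic_distances(tree).to_numpy().max()
        V = covariance_matrix(tree, CovarianceSpec("martins_hansen", alpha)).to_numpy()
        off = V - np.diag(np.diag(V))
        assert np.abs(off).max() < 1e-6
        np.testing.assert_allclose(np.diag(V), 1.0)

    def test_martins_hansen_decays_with_alpha(self):
        tree = random_tree(13, n_tips=12)
        small = covariance_matrix(tree, CovarianceSpec("martins_hansen", 0.1)).to_numpy()
        large = covariance_matrix(tree, CovarianceSpec("martins_hansen", 5.0)).to_numpy()
        mask = ~np.eye(12, dtype=bool)
        assert (large[mask] <= small[mask] + 1e-12).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            CovarianceSpec("pagel_lambda", 1.5)
        with pytest.raises(ValueError):
            CovarianceSpec("martins_hansen", -1.0)

    def test_unit_substitution_when_lengths_missing(self):
        tree = read_newick("((A,B),C);")
        V = covariance_matrix(tree, CovarianceSpec("brownian"))
        assert V.loc["A", "A"] == 2.0  # two unit branches root -> A
        assert V.loc["A", "B"] == 1.0


class TestPatristic:
    def test_hand_example(self, cherry_tree):
        D = patristic_distances(cherry_tree)
        assert D.loc["A", "B"] == 2
        assert D.loc["A", "C"] == 4
        assert (np.diag(D.to_numpy()) == 0).all()

    def test_star_tree_unit_branches(self):
        tree = read_newick("(A:1,B:1,C:1,D:1);")
        D = patristic_distances(tree).to_numpy()
        off = D[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 2.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_identity_with_brownian_covariance(self, seed):
        tree = random_tree(seed, n_tips=16)
        V = covariance_matrix(tree, CovarianceSpec("brownian")).to_numpy()
        D = patristic_distances(tree).to_numpy()
        d = np.diag(V)
        np.testing.assert_allclose(D, d[:, None] + d[None, :] - 2 * V, atol=1e-12)


class TestTreeQueries:
    def test_mrca_single_tip_is_itself(self, cherry_tree):
        v = mrca(cherry_tree, {"A"})
        assert cherry_tree.tip_label(v) == "A"

    def test_mrca_across_root_children_is_root(self, cherry_tree):
        assert mrca(cherry_tree, {"A", "C"}) == cherry_tree.root

    def test_mrca_unknown_tip_rejected(self, cherry_tree):
        with pytest.raises(KeyError):
            mrca(cherry_tree, {"A", "Z"})

    @pytest.mark.parametrize("seed", range(4))
    def test_mrca_matches_root_path_intersection(self, seed):
        tree = random_tree(seed, n_tips=12)
        rng = np.random.default_rng(seed)
        labels = rng.choice(tree.tip_labels(), size=4, replace=False)

        def path_set(label):
            v = tree.node_for_label(label)
            out = {v}
            while (p := tree.parent(v)) is not None:
                out.add(p)
                v = p
            return out

        shared = set.intersection(*[path_set(lab) for lab in labels])
        depths = tree.node_depths()
        deepest = max(shared, key=lambda v: depths[v])
        assert mrca(tree, set(labels)) == deepest

    def test_extract_subtree_at_root_is_identity(self, cherry_tree):
        sub = extract_subtree(cherry_tree, cherry_tree.root)
        assert write_newick(sub) == write_newick(cherry_tree)

    def test_extract_subtree_at_tip(self, cherry_tree):
        tip = cherry_tree.node_for_label("C")
        sub = extract_subtree(cherry_tree, tip)
        assert sub.n_tips == 1 and sub.tip_labels() == ["C"]

    def test_subtree_tips_equal_descendant_set(self):
        tree = random_tree(21, n_tips=20)
        node = tree.children(tree.root)[0]
        sub = extract_subtree(tree, node)
        expected = {tree.tip_label(v) for v in tree.descendant_tips(node)}
        assert set(sub.tip_labels()) == expected

    def test_prune_merges_branch_lengths(self):
        tree = read_newick("(((A:1,B:1):2,C:1):1,D:5);")
        sub = prune_to_tips(tree, {"A", "B", "D"})
        D = patristic_distances(sub)
        assert D.loc["A", "B"] == 2.0
        assert D.loc["A", "D"] == 9.0  # 1+2+1 up to root, plus 5 down


class TestAssignClades:
    def test_three_root_children(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1,E:2);")
        clades = assign_clades(tree)
        assert len(set(clades.values())) == 3

    def test_balanced_tree_splits_evenly(self):
        tree = make_balanced_tree(8)
        clades = assign_clades(tree)
        counts = {}
        for c in clades.values():
            counts[c] = counts.get(c, 0) + 1
        assert sorted(counts.values()) == [128, 128]

    @pytest.mark.parametrize("seed", range(3))
    def test_partition_is_exhaustive_and_disjoint(self, seed):
        tree = random_tree(seed, n_tips=25)
        clades = assign_clades(tree)
        assert set(clades) == set(tree.tip_labels())
        n_children = len(tree.children(tree.root))
        assert set(clades.values()) <= set(range(n_children))
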