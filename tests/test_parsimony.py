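"""Fitch scoring, fit indices, heuristic/exhaustive search, bootstrap, reweighting."""

import dendropy
import numpy as np
import pytest
from dendropy.model.parsimony import fitch_down_pass

from cephalon.cladistics import (
    CharacterMatrix,
    Tree,
    bootstrap,
    char_bounds,
    ci_ri,
    enumerate_topologies,
    exhaustive_search,
    fitch_length,
    heuristic_search,
    random_binary_tree,
    rf_distance,
    strict_consensus,
    successive_reweight,
    write_nexus,
)
from cephalon.synthetic import SimTreeModel, simulate_characters


def _random_matrix(rng, n_taxa, n_chars, missing=0.1):
    chars = rng.integers(0, 2, size=(n_taxa, n_chars)).astype(np.int8)
    miss = rng.random(chars.shape) < missing
    chars[miss] = -1
    return CharacterMatrix([f"t{i}" for i in range(n_taxa)], chars)


def _perfect_matrix(tree, repeats=3):
    """Homoplasy-free matrix whose characters are the tree's own splits."""
    taxa = tree.taxa
    cols = []
    for s in sorted(tree.splits(taxa)):
        cols.append([(s >> i) & 1 for i in range(len(taxa))])
    chars = np.array(cols, dtype=np.int8).T
    return CharacterMatrix(taxa, np.tile(chars, (1, repeats)))


class TestFitchLength:
    def test_constant_character_zero_steps(self):
        m = CharacterMatrix(list("ABCD"), np.zeros((4, 3), dtype=np.int8))
        t = Tree.from_newick("((A,B),(C,D));", rooted=False)
        assert fitch_length(t, m)[0] == 0

    def test_hand_scored_quartet(self):
        m = CharacterMatrix(list("ABCD"), np.array([[0], [0], [1], [1]], dtype=np.int8))
        good = Tree.from_newick("((A,B),(C,D));", rooted=False)
        bad = Tree.from_newick("((A,C),(B,D));", rooted=False)
        assert fitch_length(good, m)[0] == 1
        assert fitch_length(bad, m)[0] == 2

    def test_missing_entries_never_add_steps(self):
        m0 = CharacterMatrix(list("ABCDE"), np.array(
            [[0], [0], [1], [1], [1]], dtype=np.int8))
        m1 = CharacterMatrix(list("ABCDE"), np.array(
            [[0], [-1], [1], [-1], [1]], dtype=np.int8))
        t = Tree.from_newick("((A,B),(C,(D,E)));", rooted=False)
        assert fitch_length(t, m1)[0] <= fitch_length(t, m0)[0]

    def test_agrees_with_dendropy_fitch(self, tmp_path):
        rng = np.random.default_rng(0)
        taxa = [f"t{i}" for i in range(9)]
        for seed in range(10):
            mat = _random_matrix(rng, 9, 25)
            path = tmp_path / f"m{seed}.nex"
            write_nexus(mat, path)
            dm = dendropy.StandardCharacterMatrix.get(
                path=str(path), schema="nexus", preserve_underscores=True
            )
            tree = random_binary_tree(taxa, rng)
            dt = dendropy.Tree.get(
                data=tree.to_newick(), schema="newick",
                taxon_namespace=dm.taxon_namespace, preserve_underscores=True,
            )
            score = fitch_down_pass(
                dt.postorder_node_iter(),
                taxon_state_sets_map=dm.taxon_state_sets_map(gaps_as_missing=True),
            )
            assert fitch_length(tree, mat)[0] == score

    def test_weighted_length_is_weight_dot_steps(self):
        rng = np.random.default_rng(1)
        mat = _random_matrix(rng, 6, 15)
        mat = mat.with_weights(rng.uniform(0, 2, 15).round(3))
        t = random_binary_tree(mat.taxa, rng)
        length, steps = fitch_length(t, mat)
        assert length == pytest.approx(float(np.dot(mat.weights, steps)))

    def test_length_at_least_sum_of_minima(self):
        rng = np.random.default_rng(2)
        for seed in range(10):
            mat = _random_matrix(rng, 7, 20)
            t = random_binary_tree(mat.taxa, rng)
            minima, _ = char_bounds(mat)
            assert fitch_length(t, mat)[0] >= minima.sum()


class TestCharBounds:
    def test_counting_examples(self):
        col_all0 = np.array([[0], [0], [0], [-1], [-1]], dtype=np.int8)
        m, g = char_bounds(CharacterMatrix(list("ABCDE"), col_all0))
        assert (m[0], g[0]) == (0, 0)
        col = np.array([[0]] * 5 + [[1]] * 3, dtype=np.int8)
        m, g = char_bounds(CharacterMatrix(list("ABCDEFGH"), col))
        assert (m[0], g[0]) == (1, 3)

    def test_maximum_equals_worst_tree_by_enumeration(self):
        """g_i equals the max Fitch steps over all 105 six-taxon trees."""
        rng = np.random.default_rng(3)
        taxa = [f"t{i}" for i in range(6)]
        for _ in range(8):
            col = rng.integers(0, 2, size=(6, 1)).astype(np.int8)
            if rng.random() < 0.3:
                col[rng.integers(6), 0] = -1
            mat = CharacterMatrix(taxa, col)
            _, g = char_bounds(mat)
            worst = max(
                fitch_length(t, mat)[0] for t in enumerate_topologies(taxa)
            )
            assert g[0] == worst


class TestCiRi:
    def test_homoplasy_free_matrix_scores_one(self):
        tree = random_binary_tree([f"s{i}" for i in range(7)], np.random.default_rng(4))
        mat = _perfect_matrix(tree)
        res = exhaustive_search(mat)
        assert res.ci == 1.0 and res.ri == 1.0

    def test_quartet_homoplasy_example(self):
        # 0,1,0,1 on ((A,B),(C,D)): s=2, m=1, g=2 -> char CI 0.5, char RI 0
        mat = CharacterMatrix(list("ABCD"), np.array([[0], [1], [0], [1]], dtype=np.int8))
        tree = Tree.from_newick("((A,B),(C,D));", rooted=False)
        _, steps = fitch_length(tree, mat)
        minima, maxima = char_bounds(mat)
        assert (steps[0], minima[0], maxima[0]) == (2, 1, 2)
        out = ci_ri(steps, minima, maxima)
        assert out["ci"] == pytest.approx(0.5)
        assert out["ri"] == pytest.approx(0.0)

    def test_all_constant_flagged_undefined(self):
        mat = CharacterMatrix(list("ABCD"), np.zeros((4, 2), dtype=np.int8))
        tree = Tree.from_newick("((A,B),(C,D));", rooted=False)
        _, steps = fitch_length(tree, mat)
        out = ci_ri(steps, *char_bounds(mat))
        assert out["ci_undefined"] and out["ci"] == 1.0

    def test_rc_in_unit_interval(self):
        rng = np.random.default_rng(5)
        mat = _random_matrix(rng, 8, 40)
        res = exhaustive_search(mat)
        assert np.all(res.rc_best_fit >= 0) and np.all(res.rc_best_fit <= 1)


class TestSearch:
    def test_perfect_data_recovers_true_tree(self):
        tree = random_binary_tree([f"s{i}" for i in range(10)], np.random.default_rng(6))
        mat = _perfect_matrix(tree)
        res = heuristic_search(mat, n_replicates=5, seed=0)
        assert res.best_length == res.minima.sum()
        assert res.n_trees == 1
        assert rf_distance(res.trees[0], tree) == 0

    def test_heuristic_matches_exhaustive_on_random_data(self):
        rng = np.random.default_rng(7)
        for trial in range(10):
            mat = _random_matrix(rng, 7, 15)
            ex = exhaustive_search(mat)
            he = heuristic_search(mat, n_replicates=5, seed=trial)
            assert he.best_length == ex.best_length
            ex_keys = {t.topology_key() for t in ex.trees}
            he_keys = {t.topology_key() for t in he.trees}
            assert he_keys <= ex_keys

    def test_mpt_closure_finds_complete_optimal_set(self):
        rng = np.random.default_rng(8)
        for trial in range(5):
            mat = _random_matrix(rng, 6, 8, missing=0.3)
            ex = exhaustive_search(mat)
            he = heuristic_search(mat, n_replicates=10, seed=trial)
            assert {t.topology_key() for t in he.trees} == {
                t.topology_key() for t in ex.trees
            }

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        mat = _random_matrix(rng, 8, 30)
        a = heuristic_search(mat, n_replicates=4, seed=5)
        b = heuristic_search(mat, n_replicates=4, seed=5)
        assert a.best_length == b.best_length
        assert [t.to_newick() for t in a.trees] == [t.to_newick() for t in b.trees]

    def test_exhaustive_refuses_large_and_small(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ValueError):
            exhaustive_search(_random_matrix(rng, 10, 5))
        with pytest.raises(ValueError):
            heuristic_search(_random_matrix(rng, 3, 5))

    def test_topology_recovery_from_simulated_characters(self):
        """Strict consensus recovers a 12-taxon generating topology (RF = 0)."""
        taxa = [f"sp{i:02d}" for i in range(12)]
        tree = random_binary_tree(taxa, np.random.default_rng(0), branch_length=0.1)
        mat = simulate_characters(SimTreeModel(tree=tree, n_chars=500, seed=1))
        res = heuristic_search(mat, n_replicates=3, seed=2)
        assert rf_distance(strict_consensus(res.trees), tree) == 0


class TestBootstrap:
    def test_single_replicate_frequencies_are_all_or_nothing(self):
        rng = np.random.default_rng(11)
        mat = _random_matrix(rng, 6, 20)
        table = bootstrap(mat, B=1, seed=0)
        assert set(table.frequencies.values()) <= {0.0, 100.0}

    def test_invariant_to_taxon_order_permutation(self):
        # exact for decisive data: the optimum does not depend on the taxon
        # input order, and resampling counts depend only on the seed
        tree = random_binary_tree([f"t{i}" for i in range(6)], np.random.default_rng(12))
        mat = _perfect_matrix(tree, repeats=3)
        perm = [3, 1, 5, 0, 2, 4]
        mat_p = CharacterMatrix([mat.taxa[i] for i in perm], mat.chars[perm])
        ta = bootstrap(mat, B=30, seed=3)
        tb = bootstrap(mat_p, B=30, seed=3)

        def canonical(table):
            out = {}
            full = set(table.taxon_order)
            for group, pct in table.named():
                side = frozenset(group)
                if "t0" in side:
                    side = frozenset(full - side)
                out[side] = pct
            return out

        assert canonical(ta) == canonical(tb)

    def test_strong_signal_supports_true_splits(self):
        # 8 copies per split keep the chance of a split vanishing from a
        # resample below 1e-4, so every true split should sit at ~100 %
        tree = random_binary_tree([f"s{i}" for i in range(8)], np.random.default_rng(13))
        mat = _perfect_matrix(tree, repeats=8)
        table = bootstrap(mat, B=200, seed=4)
        for s in tree.splits(mat.taxa):
            assert table.frequencies.get(s, 0.0) >= 99.0

    def test_support_grows_with_signal(self):
        """Bootstrap support of a split rises with its character support."""
        rng = np.random.default_rng(14)
        taxa = [f"t{i}" for i in range(6)]
        tree = Tree.from_newick("(((t0,t1),(t2,t3)),(t4,t5));", rooted=False)
        target = next(
            s for s in tree.splits(taxa) if bin(s).count("1") == 2
        )
        supports = []
        for n_signal in (1, 4, 12):
            cols = [[(target >> i) & 1 for i in range(6)]] * n_signal
            noise = rng.integers(0, 2, size=(20, 6)).tolist()
            chars = np.array(cols + noise, dtype=np.int8).T
            mat = CharacterMatrix(taxa, chars)
            t = bootstrap(mat, B=60, seed=5)
            supports.append(t.frequencies.get(target, 0.0))
        assert supports[0] <= supports[1] <= supports[2]
        assert supports[2] > supports[0]


class TestSuccessiveReweight:
    def test_homoplasy_free_stabilises_in_one_round(self):
        tree = random_binary_tree([f"s{i}" for i in range(7)], np.random.default_rng(15))
        out = successive_reweight(_perfect_matrix(tree), seed=0, n_replicates=3)
        assert out["rounds_to_stable"] == 1
        assert out["converged"]
        assert np.allclose(out["weights_trajectory"][-1], 1.0)

    def test_weights_stay_in_unit_interval(self):
        rng = np.random.default_rng(16)
        mat = _random_matrix(rng, 8, 30)
        out = successive_reweight(mat, seed=1, n_replicates=3, max_rounds=6)
        for w in out["weights_trajectory"]:
            assert np.all(w >= 0) and np.all(w <= 1)

    def test_reports_round_count_and_convergence(self):
        rng = np.random.default_rng(17)
        mat = _random_matrix(rng, 8, 40)
        out = successive_reweight(mat, seed=2, n_replicates=3, max_rounds=8)
        assert 1 <= out["rounds_to_stable"] <= 8
        assert isinstance(out["converged"], bool)
        assert out["final_result"].n_trees >= 1
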