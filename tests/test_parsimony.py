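import numpy as np
import pytest

from archaeostyle.errors import (
    InvalidInputError,
    NexusParseError,
    UndefinedIndexError,
)
from archaeostyle.parsimony import (
    CharacterMatrix,
    char_step_bounds,
    ensemble_indices,
    fitch_length,
    fitch_steps,
    parse_ranges,
    read_nexus,
    subset_characters,
    write_nexus,
)
from archaeostyle.trees import UnrootedTree, all_topologies

from conftest import brute_force_steps, random_binary_matrix

TOY_NEXUS = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=4 NCHAR=3;
FORMAT DATATYPE=STANDARD MISSING=? GAP=- SYMBOLS="012";
MATRIX
Alpha  001
Beta   0?1
Gamma  {01}-2
Delta  110
;
END;
"""


class TestCharacterMatrix:
    def test_empty_cell_rejected(self):
        with pytest.raises(InvalidInputError):
            CharacterMatrix(("A", "B", "C"), np.array([[1], [0], [1]]), "01")

    def test_duplicate_taxa_rejected(self):
        with pytest.raises(InvalidInputError):
            CharacterMatrix(("A", "A", "B"), np.ones((3, 1), int), "01")

    def test_state_outside_symbol_space_rejected(self):
        with pytest.raises(InvalidInputError):
            CharacterMatrix(("A", "B", "C"), np.array([[1], [4], [1]]), "01")


class TestNexusIO:
    def test_toy_block(self, tmp_path):
        path = tmp_path / "toy.nex"
        path.write_text(TOY_NEXUS)
        m = read_nexus(path)
        assert m.taxa == ("Alpha", "Beta", "Gamma", "Delta")
        assert m.n_characters == 3
        assert m.symbols == "012"
        assert m.masks[0].tolist() == [0b001, 0b001, 0b010]

    def test_missing_is_full_state_set(self, tmp_path):
        path = tmp_path / "toy.nex"
        path.write_text(TOY_NEXUS)
        m = read_nexus(path)
        assert m.masks[1, 1] == m.full_mask()  # '?'
        assert m.masks[2, 1] == m.full_mask()  # '-' treated as missing

    def test_polymorphism_parsed_as_state_set(self, tmp_path):
        path = tmp_path / "toy.nex"
        path.write_text(TOY_NEXUS)
        m = read_nexus(path)
        assert m.masks[2, 0] == 0b011  # {01}

    def test_dimension_mismatch_raises(self, tmp_path):
        bad = TOY_NEXUS.replace("NCHAR=3", "NCHAR=4")
        path = tmp_path / "bad.nex"
        path.write_text(bad)
        with pytest.raises(NexusParseError):
            read_nexus(path)

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        m = random_binary_matrix(rng, 6, 12, n_states=3, missing_p=0.2)
        path = tmp_path / "rt.nex"
        write_nexus(m, path)
        back = read_nexus(path)
        assert back.taxa == m.taxa
        # symbol spaces may differ in breadth; compare cell state sets
        for i in range(m.n_taxa):
            for j in range(m.n_characters):
                orig = int(m.masks[i, j])
                got = int(back.masks[i, j])
                if orig == m.full_mask():
                    assert got == back.full_mask()
                else:
                    assert got == orig


class TestFitch:
    def test_single_origin_character(self, quartet_tree):
        m = CharacterMatrix(("A", "B", "C", "D"), np.array([[1], [1], [2], [2]]), "01")
        length, steps = fitch_length(quartet_tree, m)
        assert length == 1 and steps.tolist() == [1]

    def test_incongruent_arrangement_costs_two(self):
        # same character on ((A,C),(B,D))
        t = UnrootedTree(4)
        edge = next(e for e in t.edges() if 1 in e)
        t.attach_leaf(3, edge)  # pairs 1 with 3 -> groups (A,C) vs (B,D)
        m = CharacterMatrix(("A", "B", "C", "D"), np.array([[1], [1], [2], [2]]), "01")
        length, _ = fitch_length(t, m)
        assert length == 2
        assert brute_force_steps(t, m).tolist() == [2]

    def test_missing_never_adds_steps(self, quartet_tree):
        full = CharacterMatrix(("A", "B", "C", "D"),
                               np.array([[1], [1], [2], [2]]), "01")
        with_missing = CharacterMatrix(("A", "B", "C", "D"),
                                       np.array([[1], [1], [3], [2]]), "01")
        assert fitch_length(quartet_tree, with_missing)[0] <= fitch_length(
            quartet_tree, full)[0]

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(4, 7))
            m = random_binary_matrix(rng, n, int(rng.integers(2, 8)),
                                     n_states=int(rng.integers(2, 4)),
                                     missing_p=0.15)
            t = UnrootedTree(n)
            for leaf in range(3, n):
                edges = t.edges()
                t.attach_leaf(leaf, edges[rng.integers(0, len(edges))])
            np.testing.assert_array_equal(fitch_steps(t, m), brute_force_steps(t, m))

    def test_length_independent_of_rooting_choice(self):
        # scoring must not depend on which leaf anchors the traversal:
        # relabelled taxa give identical lengths
        rng = np.random.default_rng(43)
        m = random_binary_matrix(rng, 6, 10)
        t = UnrootedTree(6)
        for leaf in range(3, 6):
            edges = t.edges()
            t.attach_leaf(leaf, edges[rng.integers(0, len(edges))])
        perm = rng.permutation(6)
        m2 = CharacterMatrix(tuple(m.taxa[p] for p in perm), m.masks[perm], m.symbols)
        # build the same topology under permuted labels
        inv = np.argsort(perm)
        t2 = UnrootedTree(6, adj={
            (int(inv[k]) if k < 6 else k): {int(inv[v]) if v < 6 else v
                                            for v in vs}
            for k, vs in t.adj.items()})
        assert fitch_length(t, m)[0] == fitch_length(t2, m2)[0]

    def test_weighted_length(self, quartet_tree):
        m = CharacterMatrix(("A", "B", "C", "D"),
                            np.array([[1, 1], [1, 2], [2, 1], [2, 2]]), "01",
                            weights=np.array([3, 1]))
        length, steps = fitch_length(quartet_tree, m)
        assert steps.tolist() == [1, 2]
        assert length == 3 * 1 + 1 * 2

    def test_taxon_count_mismatch(self, quartet_tree):
        m = CharacterMatrix(("A", "B", "C"), np.ones((3, 1), int), "01")
        with pytest.raises(InvalidInputError):
            fitch_length(quartet_tree, m)


class TestStepBounds:
    def test_binary_split(self):
        m = CharacterMatrix(("A", "B", "C", "D"), np.array([[1], [1], [2], [2]]), "01")
        mb, gb = char_step_bounds(m)
        assert (mb[0], gb[0]) == (1, 2)

    def test_invariant_character(self):
        m = CharacterMatrix(("A", "B", "C", "D"), np.array([[1], [1], [1], [1]]), "01")
        mb, gb = char_step_bounds(m)
        assert (mb[0], gb[0]) == (0, 0)

    def test_three_states_with_missing(self):
        # states 0,0,1,1,2,? over six taxa
        m = CharacterMatrix(tuple("ABCDEF"),
                            np.array([[1], [1], [2], [2], [4], [7]]), "012")
        mb, gb = char_step_bounds(m)
        assert (mb[0], gb[0]) == (2, 3)

    def test_g_attained_by_some_tree(self):
        # exhaustive check on the 5 coded taxa: max over all trees equals g
        m = CharacterMatrix(tuple("ABCDE"),
                            np.array([[1], [1], [2], [2], [4]]), "012")
        _, gb = char_step_bounds(m)
        worst = max(fitch_length(t, m)[0] for t in all_topologies(5))
        assert worst == gb[0] == 3

    def test_bounds_bracket_observed_on_all_trees(self):
        rng = np.random.default_rng(44)
        m = random_binary_matrix(rng, 6, 6, n_states=3, missing_p=0.1)
        mb, gb = char_step_bounds(m)
        for t in list(all_topologies(6))[::7]:
            s = fitch_steps(t, m)
            assert np.all(mb <= s) and np.all(s <= gb)


class TestEnsembleIndices:
    def test_homoplasy_free_matrix(self, quartet_tree):
        m = CharacterMatrix(("A", "B", "C", "D"),
                            np.array([[1], [1], [2], [2]]), "01")
        _, steps = fitch_length(quartet_tree, m)
        fit = ensemble_indices(steps, m)
        assert (fit.ci, fit.ri, fit.rc) == (1.0, 1.0, 1.0)

    def test_toy_hand_computation(self, quartet_tree):
        # chars (0,0,1,1) and (0,1,0,1): s = 1+2, m = 2, g = 4
        m = CharacterMatrix(("A", "B", "C", "D"),
                            np.array([[1, 1], [1, 2], [2, 1], [2, 2]]), "01")
        _, steps = fitch_length(quartet_tree, m)
        fit = ensemble_indices(steps, m)
        assert fit.ci == pytest.approx(2 / 3)
        assert fit.ri == pytest.approx(1 / 2)
        assert fit.rc == pytest.approx(1 / 3)

    def test_rc_equals_ci_times_ri(self):
        rng = np.random.default_rng(45)
        for _ in range(50):
            n = int(rng.integers(4, 7))
            m = random_binary_matrix(rng, n, int(rng.integers(3, 10)))
            t = UnrootedTree(n)
            for leaf in range(3, n):
                edges = t.edges()
                t.attach_leaf(leaf, edges[rng.integers(0, len(edges))])
            try:
                fit = ensemble_indices(fitch_steps(t, m), m)
            except UndefinedIndexError:
                continue
            assert fit.rc == pytest.approx(fit.ci * fit.ri, abs=1e-15)

    def test_all_invariant_matrix_undefined(self, quartet_tree):
        m = CharacterMatrix(("A", "B", "C", "D"), np.ones((4, 2), int), "01")
        with pytest.raises(UndefinedIndexError):
            ensemble_indices(fitch_steps(quartet_tree, m), m)


class TestSubset:
    def _matrix(self, n_chars=230):
        rng = np.random.default_rng(46)
        return random_binary_matrix(rng, 5, n_chars)

    def test_paper_style_ranges(self):
        m = self._matrix()
        sub = subset_characters(m, include_ranges=[(1, 4), (100, 180)])
        assert sub.n_characters == 85
        assert sub.orig_indices[0] == 1 and sub.orig_indices[-1] == 180

    def test_scale_partition_width(self):
        sub = subset_characters(self._matrix(), include_ranges=[(5, 48)])
        assert sub.n_characters == 44

    def test_full_range_is_identity(self):
        m = self._matrix()
        sub = subset_characters(m, include_ranges=[(1, 230)])
        np.testing.assert_array_equal(sub.masks, m.masks)

    def test_exclusion_complements_inclusion(self):
        m = self._matrix()
        inc = subset_characters(m, include_ranges=[(1, 4), (100, 180)])
        exc = subset_characters(m, exclude_ranges=[(5, 99), (181, 230)])
        np.testing.assert_array_equal(inc.masks, exc.masks)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            subset_characters(self._matrix(), include_ranges=[(200, 231)])

    def test_both_modes_rejected(self):
        with pytest.raises(InvalidInputError):
            subset_characters(self._matrix(), include_ranges=[(1, 2)],
                              exclude_ranges=[(3, 4)])

    def test_parse_ranges(self):
        assert parse_ranges("1-4,100-180,7") == [(1, 4), (100, 180), (7, 7)]


class TestDendropyCrossCheck:
    def test_length_agrees_with_independent_scorer(self, tmp_path):
        import dendropy
        from dendropy.model.parsimony import fitch_down_pass

        from archaeostyle.synthetic import MkSimulationSpec, simulate_matrix, simulate_tree

        tree = simulate_tree(8, seed=2, total_depth=0.4)
        m = simulate_matrix(MkSimulationSpec(tree=tree, n_characters=30,
                                             missing_fraction=0.1, seed=3))
        topo = tree.topology(8)
        mine, _ = fitch_length(topo, m)
        path = tmp_path / "m.nex"
        write_nexus(m, path)
        dmat = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
        dtree = dendropy.Tree.get(data=topo.to_newick(m.taxa), schema="newick",
                                  taxon_namespace=dmat.taxon_namespace)
        tsm = dmat.taxon_state_sets_map(gaps_as_missing=True)
        assert fitch_down_pass(dtree.postorder_node_iter(),
                               taxon_state_sets_map=tsm) == mine
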