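"""Expression trees: evaluation, counting, enumeration, serialisation."""

import itertools
import string

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from logicscape.network import GRN, decode_state, random_grn
from logicscape.operators import builtin_operators, operator_set
from logicscape.trees import (
    Configuration,
    Leaf,
    Node,
    canonical_form,
    count_configs,
    evaluate_tree,
    evaluate_tree_all_states,
    exhaustive_configurations,
    exhaustive_search_space,
    format_tree,
    parse_tree,
    sample_configuration,
    total_configs,
)

ALL6 = builtin_operators()


class TestEvaluation:
    @pytest.fixture
    def two_input_grn(self):
        return GRN(("B", "E", "C"), (("B", "C", 1), ("E", "C", 1)))

    def test_leaf_effects_follow_edge_sign(self):
        grn = GRN(("A", "T"), (("A", "T", 1),))
        assert evaluate_tree(Leaf("A"), (1, 0), grn, "T") == 1
        assert evaluate_tree(Leaf("A"), (0, 0), grn, "T") == 0
        rep = GRN(("A", "T"), (("A", "T", -1),))
        assert evaluate_tree(Leaf("A"), (1, 0), rep, "T") == -1
        assert evaluate_tree(Leaf("A"), (0, 0), rep, "T") == 0

    def test_two_activators_on(self, two_input_grn):
        tree = Node("OR_HI", Leaf("B"), Leaf("E"))
        assert evaluate_tree(tree, (1, 1, 0), two_input_grn, "C") == 1

    def test_empty_tree_is_neutral(self):
        grn = GRN(("LIF",), ())
        assert evaluate_tree(None, (1,), grn, "LIF") == 0
        assert evaluate_tree(None, (0,), grn, "LIF") == 0

    def test_state_index_and_bit_vector_agree(self, two_input_grn):
        tree = Node("AND_HI", Leaf("B"), Leaf("E"))
        for s in range(8):
            bits = decode_state(s, 3)
            assert evaluate_tree(tree, s, two_input_grn, "C") == evaluate_tree(
                tree, bits, two_input_grn, "C"
            )

    def test_vectorized_matches_scalar(self, two_input_grn):
        tree = Node("MIN", Leaf("B"), Leaf("E"))
        vec = evaluate_tree_all_states(tree, two_input_grn, "C")
        for s in range(8):
            assert vec[s] == evaluate_tree(tree, s, two_input_grn, "C")

    def test_foreign_leaf_rejected(self, two_input_grn):
        with pytest.raises(KeyError):
            evaluate_tree(Leaf("C"), (1, 1, 1), two_input_grn, "C")


class TestCounting:
    @pytest.mark.parametrize(
        "p,k,expected",
        [(6, 1, 1), (2, 2, 2), (6, 2, 6), (2, 3, 8), (6, 4, 1536)],
    )
    def test_closed_form_values(self, p, k, expected):
        assert count_configs(p, k) == expected

    @pytest.mark.parametrize("p", range(2, 7))
    def test_recursion(self, p):
        for k in range(3, 8):
            assert count_configs(p, k) == count_configs(p, k - 1) * (3 * p - 2)

    def test_total_configs_printed_values(self, mef_ipsc, pluripotency):
        assert total_configs(mef_ipsc[0], 6) == 26142282979403407520956416
        assert total_configs(pluripotency[0], 6) == 28179280429056

    def test_total_is_one_for_indegrees_at_most_one(self):
        g = GRN(("A", "B", "C"), (("A", "B", 1), ("B", "C", 1)))
        for p in (1, 2, 6):
            assert total_configs(g, p) == 1

    def test_non_positive_arguments_rejected(self):
        with pytest.raises(ValueError):
            count_configs(0, 3)


class TestExhaustiveEnumeration:
    def test_three_regulators_two_operators_gives_eight(self):
        trees = list(exhaustive_configurations(["A", "B", "C"], operator_set("bar")))
        assert len(trees) == 8
        assert len({canonical_form(t) for t in trees}) == 8
        # the two single-operator runs plus 3+3 mixed forms
        ops_used = [sorted({n.op for n in _nodes(t)}) for t in trees]
        assert sum(len(o) == 1 for o in ops_used) == 2
        assert sum(len(o) == 2 for o in ops_used) == 6

    def test_two_regulators_yield_one_tree_per_operator(self):
        trees = list(exhaustive_configurations(["A", "B"], ALL6))
        assert [t.op for t in trees] == [op.name for op in ALL6]

    @pytest.mark.parametrize("p", range(2, 7))
    @pytest.mark.parametrize("k", range(1, 6))
    def test_count_matches_closed_form_with_no_duplicates(self, p, k):
        regs = list(string.ascii_uppercase[:k])
        forms = set()
        n = 0
        for tree in exhaustive_configurations(regs, ALL6[:p]):
            forms.add(canonical_form(tree))
            n += 1
            assert sorted(tree.leaves) == regs
        assert n == count_configs(p, k)
        assert len(forms) == n

    def test_starts_from_left_heavy_single_operator_tree(self):
        first = next(iter(exhaustive_configurations(["A", "B", "C", "D"], ALL6)))
        # ((A op B) op C) op D with the first operator throughout
        assert format_tree(first) == "(AND_HI (AND_HI (AND_HI A B) C) D)"

    def test_empty_regulator_list_rejected(self):
        with pytest.raises(ValueError):
            list(exhaustive_configurations([], ALL6))


def _nodes(tree):
    if isinstance(tree, Leaf):
        return []
    return [tree] + _nodes(tree.left) + _nodes(tree.right)


class TestSearchSpace:
    def test_product_of_per_target_counts(self):
        g = GRN(
            ("A", "B", "C", "X", "Y"),
            (
                ("A", "X", 1), ("B", "X", 1),
                ("A", "Y", 1), ("B", "Y", 1), ("C", "Y", -1),
            ),
        )
        configs = list(exhaustive_search_space(g, operator_set("bar")))
        assert len(configs) == 2 * 8
        assert len({tuple(sorted(c.to_json().items())) for c in configs}) == 16

    def test_single_configuration_when_all_indegrees_at_most_one(self):
        g = GRN(("A", "B"), (("A", "B", 1),))
        configs = list(exhaustive_search_space(g, ALL6))
        assert len(configs) == 1 and configs[0]["B"] == Leaf("A")

    def test_restartable_and_deterministic(self, toy):
        grn, _ = toy
        a = [c.to_json() for c in exhaustive_search_space(grn, operator_set("bar"))]
        b = [c.to_json() for c in exhaustive_search_space(grn, operator_set("bar"))]
        assert a == b

    def test_guard_triggers(self, mef_ipsc):
        with pytest.raises(ValueError, match="guard"):
            next(iter(exhaustive_search_space(mef_ipsc[0], ALL6)))


class TestStochasticSampling:
    def test_seed_reproducibility(self, toy):
        grn, _ = toy
        a = sample_configuration(grn, ALL6, np.random.default_rng(5))
        b = sample_configuration(grn, ALL6, np.random.default_rng(5))
        assert a.to_json() == b.to_json()

    def test_single_regulator_always_leaf(self):
        g = GRN(("A", "B"), (("A", "B", 1),))
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert sample_configuration(g, ALL6, rng)["B"] == Leaf("A")

    def test_operator_labels_approximately_uniform(self):
        from scipy.stats import chisquare

        g = GRN(("A", "B", "T"), (("A", "T", 1), ("B", "T", 1)))
        rng = np.random.default_rng(123)
        counts = {op.name: 0 for op in ALL6}
        n = 6000
        for _ in range(n):
            counts[sample_configuration(g, ALL6, rng)["T"].op] += 1
        stat, pvalue = chisquare(list(counts.values()))
        assert pvalue > 1e-4  # uniform at 1/6 each

    def test_leaf_multiset_preserved(self, mef_ipsc):
        grn, _ = mef_ipsc
        cfg = sample_configuration(grn, ALL6, np.random.default_rng(9))
        cfg.validate(grn)  # leaves of every tree equal the regulator set


@st.composite
def random_tree(draw, leaves):
    if len(leaves) == 1:
        return Leaf(leaves[0])
    cut = draw(st.integers(1, len(leaves) - 1))
    op = draw(st.sampled_from([o.name for o in ALL6]))
    return Node(op, draw(random_tree(leaves[:cut])), draw(random_tree(leaves[cut:])))


class TestCanonicalInvariance:
    @given(st.data())
    @settings(deadline=None, max_examples=60)
    def test_evaluation_invariant_under_commutativity_and_reassociation(self, data):
        k = data.draw(st.integers(2, 4))
        leaves = list(string.ascii_uppercase[:k])
        tree = data.draw(random_tree(leaves))
        mutated = data.draw(st.sampled_from(_equivalent_rewrites(tree)))
        grn = GRN(
            tuple(leaves) + ("T",),
            tuple((g, "T", data.draw(st.sampled_from([1, -1]))) for g in leaves),
        )
        assert canonical_form(tree) == canonical_form(mutated)
        for s in range(1 << k):
            bits = decode_state(s, k) + (0,)
            assert evaluate_tree(tree, bits, grn, "T") == evaluate_tree(
                mutated, bits, grn, "T"
            )


def _equivalent_rewrites(tree):
    """Commutative swaps and same-operator rotations of one tree."""
    out = []
    if isinstance(tree, Node):
        out.append(Node(tree.op, tree.right, tree.left))
        if isinstance(tree.left, Node) and tree.left.op == tree.op:
            out.append(
                Node(tree.op, tree.left.left, Node(tree.op, tree.left.right, tree.right))
            )
        out.append(Node(tree.op, tree.left, tree.right))
    else:
        out.append(tree)
    return out


class TestSerialisation:
    def test_parse_three_leaf_expression(self):
        tree = parse_tree("(AND_HI (OR_HI Stat3 Esrrb) Klf4)")
        assert sorted(tree.leaves) == ["Esrrb", "Klf4", "Stat3"]

    def test_bare_leaf(self):
        assert parse_tree("Klf4") == Leaf("Klf4")

    @given(st.data())
    @settings(deadline=None, max_examples=40)
    def test_round_trip(self, data):
        k = data.draw(st.integers(1, 4))
        tree = data.draw(random_tree(list(string.ascii_uppercase[:k])))
        assert parse_tree(format_tree(tree)) == tree

    @pytest.mark.parametrize(
        "text", ["(NOPE A B)", "(AND_HI A)", "(AND_HI A B C)", "A B", "("]
    )
    def test_malformed_rejected(self, text):
        with pytest.raises((ValueError, KeyError)):
            parse_tree(text)


class TestConfiguration:
    def test_validation_catches_wrong_leaves(self, toy):
        grn, _ = toy
        trees = {g: None for g in grn.genes}
        with pytest.raises(ValueError, match="leaves"):
            Configuration.from_trees(grn, trees)

    def test_json_round_trip(self, toy):
        grn, _ = toy
        cfg = sample_configuration(grn, ALL6, np.random.default_rng(3))
        again = Configuration.from_json(cfg.to_json(), grn)
        assert again.to_json() == cfg.to_json()
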