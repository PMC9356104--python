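"""Expression trees over regulatory inputs and configuration enumeration.

Every multi-input gene needs its regulators' effects combined into one
signal.  The combination is written as a binary expression tree: leaves
are input genes (each appearing exactly once; the edge sign from the GRN
decides whether an ON leaf contributes +1 or -1), internal nodes are
three-valued operators.  An assignment of one tree per target gene is a
*configuration*; each configuration induces a potentially distinct
energy landscape.

Because the admitted operators are commutative and associative, many
binary trees denote the same logical function.  With ``p`` operators and
``k`` inputs the number of configurations for one target is::

    N(p, 1) = 1,   N(p, 2) = p,   N(p, k) = p * (3p - 2)**(k - 2)

equivalently the recursion ``N(p, k) = N(p, k-1) * (3p - 2)``.  The
exhaustive enumerator below realises this count constructively: each
tree over the first ``k-1`` inputs is extended by the next input in
exactly ``3p - 2`` ways, and no two emitted trees share a canonical form
(flatten maximal same-operator runs, sort children).  Enumeration starts
from the maximally left-heavy single-operator tree, and operator changes
cycle faster than leaf rearrangements, the cheapest change first.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

from .network import GRN
from .operators import Operator, get_operator

__all__ = [
    "Leaf",
    "Node",
    "ExpressionTree",
    "Configuration",
    "evaluate_tree",
    "evaluate_tree_all_states",
    "canonical_form",
    "count_configs",
    "total_configs",
    "exhaustive_configurations",
    "exhaustive_search_space",
    "sample_configuration",
    "parse_tree",
    "format_tree",
]


@dataclass(frozen=True)
class Leaf:
    gene: str

    @property
    def leaves(self) -> tuple[str, ...]:
        return (self.gene,)


@dataclass(frozen=True)
class Node:
    op: str
    left: "ExpressionTree"
    right: "ExpressionTree"

    @property
    def leaves(self) -> tuple[str, ...]:
        return self.left.leaves + self.right.leaves


ExpressionTree = Leaf | Node  # an empty tree is represented by None


class Configuration(dict):
    """Map from target gene to its expression tree (``None`` for no inputs)."""

    @classmethod
    def from_trees(cls, grn: GRN, trees: Mapping[str, ExpressionTree | None]) -> "Configuration":
        cfg = cls(trees)
        cfg.validate(grn)
        return cfg

    def validate(self, grn: GRN) -> None:
        for gene in grn.genes:
            if gene not in self:
                raise ValueError(f"configuration missing target gene {gene!r}")
            tree = self[gene]
            want = sorted(src for src, _ in grn.regulators(gene))
            have = sorted(tree.leaves) if tree is not None else []
            if want != have:
                raise ValueError(
                    f"tree for {gene!r} has leaves {have}, regulators are {want}"
                )

    def to_json(self) -> dict[str, str]:
        return {g: (format_tree(t) if t is not None else "") for g, t in self.items()}

    @classmethod
    def from_json(cls, obj: Mapping[str, str], grn: GRN) -> "Configuration":
        trees = {g: (parse_tree(s) if s else None) for g, s in obj.items()}
        return cls.from_trees(grn, trees)


# ---------------------------------------------------------------------------
# Evaluation


def _leaf_effect(gene: str, bits: Mapping[str, int] | None, signs: Mapping[str, int]) -> int:
    if gene not in signs:
        raise KeyError(f"leaf gene {gene!r} is not a regulator of this target")
    value = bits[gene]
    return signs[gene] if value else 0


def evaluate_tree(
    tree: ExpressionTree | None,
    state: int | Sequence[int],
    grn: GRN,
    target: str,
) -> int:
    """Net effect of ``target``'s inputs in ``state`` (index or bit vector).

    A leaf maps its gene's expression to an effect: OFF is always
    neutral (0); ON is +1 for an activating edge, -1 for a repressing
    one.  Internal nodes combine their children with their operator.  An
    empty tree (media / no-input gene) is neutral.
    """
    if tree is None:
        return 0
    signs = dict(grn.regulators(target))
    if isinstance(state, (int, np.integer)):
        bits = {g: (int(state) >> i) & 1 for i, g in enumerate(grn.genes)}
    else:
        bits = {g: int(v) for g, v in zip(grn.genes, state)}

    def rec(t: ExpressionTree) -> int:
        if isinstance(t, Leaf):
            return _leaf_effect(t.gene, bits, signs)
        return get_operator(t.op)(rec(t.left), rec(t.right))

    return rec(tree)


def evaluate_tree_all_states(
    tree: ExpressionTree | None, grn: GRN, target: str
) -> np.ndarray:
    """Vectorised net effect of ``target``'s inputs over all 2^N states."""
    n_states = grn.n_states
    if tree is None:
        return np.zeros(n_states, dtype=np.int8)
    signs = dict(grn.regulators(target))
    idx = np.arange(n_states)

    def rec(t: ExpressionTree) -> np.ndarray:
        if isinstance(t, Leaf):
            if t.gene not in signs:
                raise KeyError(f"leaf gene {t.gene!r} is not a regulator of {target!r}")
            on = ((idx >> grn.bit(t.gene)) & 1).astype(np.int8)
            return (signs[t.gene] * on).astype(np.int8)
        table = np.asarray(get_operator(t.op).table, dtype=np.int8)
        a, b = rec(t.left), rec(t.right)
        return table[a + 1, b + 1]

    return rec(tree)


# ---------------------------------------------------------------------------
# Canonical forms
#
# Two binary trees denote the same function exactly when they agree up
# to commutative swaps and same-operator re-association.  The canonical
# form flattens maximal same-operator runs into child multisets and
# sorts children, so equality of canonical forms is the dedup oracle.


def canonical_form(tree: ExpressionTree):
    """Hashable canonical form, invariant under commutativity/associativity."""
    if isinstance(tree, Leaf):
        return ("L", tree.gene)
    children: list = []

    def collect(t: ExpressionTree, op: str) -> None:
        if isinstance(t, Node) and t.op == op:
            collect(t.left, op)
            collect(t.right, op)
        else:
            children.append(canonical_form(t))

    collect(tree, tree.op)
    return (tree.op, tuple(sorted(children, key=repr)))


# Internal multiset representation used by the enumerator:
#   leaf -> ("L", gene)
#   node -> (op, (child, child, ...))  with children canonically sorted
# and no child of a node sharing the node's operator (runs flattened).


def _m_leaves(t) -> tuple[str, ...]:
    if t[0] == "L":
        return (t[1],)
    return tuple(sorted(l for c in t[1] for l in _m_leaves(c)))


def _m_node(op: str, children: Sequence) -> tuple:
    flat: list = []
    for c in children:
        if c[0] != "L" and c[0] == op:
            flat.extend(c[1])
        else:
            flat.append(c)
    flat.sort(key=lambda c: (_m_leaves(c), repr(c)))
    return (op, tuple(flat))


def _m_to_binary(t) -> ExpressionTree:
    """Left fold a canonical multiset node into a left-heavy binary tree."""
    if t[0] == "L":
        return Leaf(t[1])
    op, children = t
    parts = [_m_to_binary(c) for c in children]
    acc = parts[0]
    for part in parts[1:]:
        acc = Node(op, acc, part)
    return acc


def count_configs(p: int, k: int) -> int:
    """Number of distinct operator configurations for one target gene.

    Exact integer arithmetic: real networks overflow 64 bits.
    """
    if p < 1 or k < 1:
        raise ValueError("p and k must be positive")
    if k == 1:
        return 1
    return p * (3 * p - 2) ** (k - 2)


def total_configs(grn: GRN, p: int) -> int:
    """Product of per-target configuration counts over the whole network."""
    total = 1
    for gene in grn.genes:
        total *= count_configs(p, max(grn.in_degree(gene), 1))
    return total


def _canon_enumerate(leaves: Sequence[str], op_names: Sequence[str]) -> Iterator:
    """Yield canonical multiset trees; exactly ``count_configs(p, k)`` of them.

    Trees over the first ``k-1`` leaves are extended by the final leaf in
    ``3p - 2`` ways: appended to the root run (1 way) and, for each
    operator differing from the root's (``p - 1`` of them), three
    placements (joined with the whole tree, with the root's first child,
    or with the root's last child).  All emitted trees are pairwise
    distinct in canonical form.
    """
    k = len(leaves)
    if k == 1:
        yield ("L", leaves[0])
        return
    if k == 2:
        for op in op_names:
            yield _m_node(op, [("L", leaves[0]), ("L", leaves[1])])
        return
    x = ("L", leaves[-1])
    for base in _canon_enumerate(leaves[:-1], op_names):
        root_op, children = base
        # append to the root's operator run
        yield _m_node(root_op, list(children) + [x])
        for op in op_names:
            if op == root_op:
                continue
            yield _m_node(op, [base, x])
            yield _m_node(root_op, [_m_node(op, [children[0], x])] + list(children[1:]))
            yield _m_node(root_op, list(children[:-1]) + [_m_node(op, [children[-1], x])])


def exhaustive_configurations(
    regulators: Sequence[str], ops: Sequence[Operator]
) -> Iterator[ExpressionTree]:
    """Stream all distinct expression trees for one target gene.

    Yields binary trees that are pairwise inequivalent under
    commutativity and associativity; the total count equals
    :func:`count_configs` of ``(len(ops), len(regulators))``.  The order
    is deterministic, starting from the maximally left-heavy tree built
    from the first operator.
    """
    if not regulators:
        raise ValueError("at least one regulator required")
    if len(set(regulators)) != len(regulators):
        raise ValueError("regulators must be distinct")
    op_names = [op.name for op in ops]
    if len(set(op_names)) != len(op_names):
        raise ValueError("duplicate operators in set")
    for canon in _canon_enumerate(list(regulators), op_names):
        yield _m_to_binary(canon)


def exhaustive_search_space(
    grn: GRN,
    ops: Sequence[Operator],
    guard: int = 10_000_000,
    force: bool = False,
) -> Iterator[Configuration]:
    """Stream every configuration of the network (Cartesian product).

    Per-target enumerations advance nested-loop style with the smallest
    trees outermost (varied least often).  Guarded against search spaces
    beyond ``guard`` landscapes unless ``force`` is set.
    """
    total = total_configs(grn, len(ops))
    if total > guard and not force:
        raise ValueError(
            f"{total} configurations exceed the guard of {guard}; pass force=True"
        )
    multi = [g for g in grn.genes if grn.in_degree(g) >= 1]
    multi.sort(key=lambda g: (grn.in_degree(g), grn.genes.index(g)))
    per_target = [
        list(exhaustive_configurations([s for s, _ in grn.regulators(g)], ops))
        for g in multi
    ]
    fixed = {g: None for g in grn.genes if grn.in_degree(g) == 0}
    for combo in itertools.product(*per_target):
        trees = dict(fixed)
        trees.update(dict(zip(multi, combo)))
        yield Configuration.from_trees(grn, trees)


def sample_configuration(
    grn: GRN, ops: Sequence[Operator], rng: np.random.Generator
) -> Configuration:
    """Draw a random configuration: per target, a uniformly split random
    binary tree shape, a random leaf order, and independent uniform
    operator labels."""
    op_names = [op.name for op in ops]

    def rand_tree(leaves: list[str]) -> ExpressionTree:
        if len(leaves) == 1:
            return Leaf(leaves[0])
        cut = int(rng.integers(1, len(leaves)))
        op = op_names[int(rng.integers(len(op_names)))]
        return Node(op, rand_tree(leaves[:cut]), rand_tree(leaves[cut:]))

    trees: dict[str, ExpressionTree | None] = {}
    for gene in grn.genes:
        regs = [s for s, _ in grn.regulators(gene)]
        if not regs:
            trees[gene] = None
        else:
            order = [regs[i] for i in rng.permutation(len(regs))]
            trees[gene] = rand_tree(order)
    return Configuration.from_trees(grn, trees)


# ---------------------------------------------------------------------------
# S-expression serialisation: "(OP lhs rhs)", leaves are gene names.

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def format_tree(tree: ExpressionTree) -> str:
    if isinstance(tree, Leaf):
        return tree.gene
    return f"({tree.op} {format_tree(tree.left)} {format_tree(tree.right)})"


def parse_tree(text: str) -> ExpressionTree:
    tokens = _TOKEN.findall(text)
    if not tokens:
        raise ValueError("empty tree expression")
    pos = 0

    def parse() -> ExpressionTree:
        nonlocal pos
        if pos >= len(tokens):
            raise ValueError("unexpected end of expression")
        tok = tokens[pos]
        pos += 1
        if tok == "(":
            if pos >= len(tokens):
                raise ValueError("unexpected end of expression")
            op = tokens[pos]
            pos += 1
            get_operator(op)  # raises on unknown operator
            left = parse()
            right = parse()
            if pos >= len(tokens) or tokens[pos] != ")":
                raise ValueError("operator nodes take exactly two children")
            pos += 1
            return Node(op, left, right)
        if tok == ")":
            raise ValueError("unexpected ')'")
        return Leaf(tok)

    tree = parse()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens: {' '.join(tokens[pos:])}")
    return tree
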