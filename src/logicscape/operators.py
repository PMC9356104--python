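"""Three-valued operator algebra for regulatory logic.

A regulatory input acts on its target through the *effect* space
``{-1, 0, +1}`` (repressive / neutral / activating), decoupled from the
input gene's binary ON/OFF *expression*.  When several inputs converge on
one target their effects are combined by a binary operator on the effect
space.  An operator is a 3x3 result table ``q(i, j)`` with
``i, j in {-1, 0, +1}``; rows and columns are ordered ``-1, 0, +1``.

Six non-trivial operators survive the requirements of idempotence,
commutativity and associativity (together with three constant-like
tables).  They are provided here under ASCII-safe canonical names:

========  ==================================================================
AND_HI    AND-like; different-sign inputs combine to +1
AND_LO    AND-like; different-sign inputs combine to -1
OR_HI     OR-like;  different-sign inputs combine to +1
OR_LO     OR-like;  different-sign inputs combine to -1
MAX       returns the maximum input effect
MIN       returns the minimum input effect
========  ==================================================================
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator, Sequence

EFFECTS: tuple[int, ...] = (-1, 0, 1)

__all__ = [
    "EFFECTS",
    "Operator",
    "NeutralEffectError",
    "builtin_operators",
    "operator_set",
    "get_operator",
    "apply_operator",
    "forcing",
    "operator_properties",
    "enumerate_operators",
    "fold",
]


class NeutralEffectError(ValueError):
    """Raised when the forcing function is applied to a neutral effect."""


@dataclass(frozen=True)
class Operator:
    """A binary operator on the effect space, stored as a 3x3 table.

    ``table[i + 1][j + 1]`` is the result of combining effects ``i`` and
    ``j`` (row/column order -1, 0, +1).
    """

    name: str
    table: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        if len(self.table) != 3 or any(len(row) != 3 for row in self.table):
            raise ValueError("operator table must be 3x3")
        for row in self.table:
            for v in row:
                if v not in EFFECTS:
                    raise ValueError(f"table entry {v!r} outside effect space")

    def __call__(self, a: int, b: int) -> int:
        return apply_operator(self, a, b)

    def to_json(self) -> dict:
        return {"name": self.name, "table": [list(r) for r in self.table]}

    @classmethod
    def from_json(cls, obj: dict) -> "Operator":
        return cls(obj["name"], tuple(tuple(r) for r in obj["table"]))


def _op(name: str, rows: Sequence[Sequence[int]]) -> Operator:
    return Operator(name, tuple(tuple(r) for r in rows))


#: The six canonical operators, in deterministic order.
_BUILTINS: tuple[Operator, ...] = (
    _op("AND_HI", [(-1, 0, 1), (0, 0, 0), (1, 0, 1)]),
    _op("AND_LO", [(-1, 0, -1), (0, 0, 0), (-1, 0, 1)]),
    _op("OR_HI", [(-1, -1, 1), (-1, 0, 1), (1, 1, 1)]),
    _op("OR_LO", [(-1, -1, -1), (-1, 0, 1), (-1, 1, 1)]),
    _op("MAX", [(-1, 0, 1), (0, 0, 1), (1, 1, 1)]),
    _op("MIN", [(-1, -1, -1), (-1, 0, 0), (-1, 0, 1)]),
)

_BY_NAME = {op.name: op for op in _BUILTINS}

#: Named operator presets.  The three two-operator pairs are balanced with
#: respect to output-value frequency; "all" is the full six-operator set.
_PRESETS = {
    "bar": ("AND_HI", "OR_HI"),
    "underbar": ("AND_LO", "OR_LO"),
    "maxmin": ("MAX", "MIN"),
    "all": tuple(op.name for op in _BUILTINS),
}


def builtin_operators() -> tuple[Operator, ...]:
    """Return the six canonical operators in deterministic order."""
    return _BUILTINS


def get_operator(name: str) -> Operator:
    """Look up a built-in operator by canonical name."""
    try:
        return _BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown operator {name!r}; known: {sorted(_BY_NAME)}") from None


def operator_set(preset: str) -> tuple[Operator, ...]:
    """Return a named preset: 'bar', 'underbar', 'maxmin' or 'all'."""
    try:
        names = _PRESETS[preset]
    except KeyError:
        raise KeyError(f"unknown operator set {preset!r}; known: {sorted(_PRESETS)}") from None
    return tuple(_BY_NAME[n] for n in names)


def apply_operator(op: Operator, a: int, b: int) -> int:
    """Apply ``op`` to effects ``a`` and ``b``."""
    if a not in EFFECTS or b not in EFFECTS:
        raise ValueError(f"effects must be in {EFFECTS}, got ({a!r}, {b!r})")
    return op.table[a + 1][b + 1]


def forcing(e: int) -> int:
    """Map a net effect to the expression value it forces on the target.

    ``+1 -> 1`` (the target should be ON), ``-1 -> 0`` (OFF).  A neutral
    effect imposes no forcing, so ``forcing(0)`` raises
    :class:`NeutralEffectError`; callers must branch on neutrality first.
    """
    if e == 1:
        return 1
    if e == -1:
        return 0
    if e == 0:
        raise NeutralEffectError("neutral effect imposes no forcing")
    raise ValueError(f"effect must be in {EFFECTS}, got {e!r}")


def operator_properties(op: Operator) -> dict[str, bool]:
    """Check idempotence, commutativity and associativity by brute force."""
    idem = all(op(i, i) == i for i in EFFECTS)
    comm = all(op(i, j) == op(j, i) for i in EFFECTS for j in EFFECTS)
    assoc = all(
        op(i, op(j, k)) == op(op(i, j), k)
        for i in EFFECTS
        for j in EFFECTS
        for k in EFFECTS
    )
    return {"idempotent": idem, "commutative": comm, "associative": assoc}


def enumerate_operators(
    require_idempotent: bool = False,
    require_commutative: bool = False,
    require_associative: bool = False,
    values: Sequence[int] = EFFECTS,
) -> list[Operator]:
    """Enumerate all binary operator tables over ``values``, filtered.

    For the three-valued effect space there are 3^9 = 19683 tables.  The
    order is deterministic: lexicographic on the flattened (row-major)
    table with values compared numerically.  Passing ``values=(0, 1)``
    enumerates the 16 two-valued Boolean operators instead.
    """
    values = tuple(values)
    m = len(values)
    index = {v: i for i, v in enumerate(values)}

    out: list[Operator] = []
    for flat in itertools.product(values, repeat=m * m):
        table = tuple(flat[i * m : (i + 1) * m] for i in range(m))

        def q(a: int, b: int) -> int:
            return table[index[a]][index[b]]

        if require_idempotent and not all(q(i, i) == i for i in values):
            continue
        if require_commutative and not all(
            q(i, j) == q(j, i) for i in values for j in values
        ):
            continue
        if require_associative and not all(
            q(i, q(j, k)) == q(q(i, j), k)
            for i in values
            for j in values
            for k in values
        ):
            continue
        name = "T" + "".join({-1: "m", 0: "z", 1: "p"}.get(v, str(v)) for v in flat)
        if values == EFFECTS:
            out.append(Operator(name, table))
        else:
            # Two-valued (or other) domains do not fit the Operator type;
            # wrap as plain table-holding operators via a light duck type.
            out.append(_RawOperator(name, table, values))
    return out


@dataclass(frozen=True)
class _RawOperator:
    """Operator over an arbitrary value domain (used for the two-valued check)."""

    name: str
    table: tuple[tuple[int, ...], ...]
    values: tuple[int, ...]

    def __call__(self, a: int, b: int) -> int:
        return self.table[self.values.index(a)][self.values.index(b)]


def fold(op: Operator, effects: Sequence[int]) -> int:
    """Combine a sequence of effects with a left fold of ``op``.

    Safe as an n-ary combination only for associative (and, for order
    independence, commutative) operators, which all built-ins are.
    """
    if not effects:
        raise ValueError("cannot fold an empty effect sequence")
    acc = effects[0]
    for e in effects[1:]:
        acc = op(acc, e)
    return acc
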