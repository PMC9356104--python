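"""Gene-regulatory-network data model and binary state encoding.

A GRN is a set of named genes plus signed directed edges
(``+1`` = activation, ``-1`` = repression).  Input nodes with no
regulators (e.g. medium components such as LIF) are flagged as *media*
genes.  A joint ON/OFF assignment of all ``N`` genes is a *cell state*,
indexed by the integer ``s = sum_i 2^i * g_i`` where the gene at list
position ``i`` owns bit ``i`` (least significant).  This bit convention
is global: every other module consumes states through this one.

Binary strings in reports are printed most-significant-bit first
(``g_{N-1} ... g_0``), so the 5-gene state ``(0,1,1,0,1)`` prints as
``"10110"`` and indexes to 22.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GRN",
    "ConstraintSet",
    "NetworkParseError",
    "encode_state",
    "decode_state",
    "state_string",
    "hamming_neighbors",
    "read_network",
    "write_network",
    "read_constraints",
    "write_constraints",
    "random_grn",
]

_SIGN_TOKENS = {"+1": 1, "1": 1, "activate": 1, "-1": -1, "−1": -1, "repress": -1}


class NetworkParseError(ValueError):
    """Raised on malformed network or constraint files."""


@dataclass(frozen=True)
class GRN:
    """A signed gene regulatory network.

    Gene order is significant: it defines the bit position of each gene
    in the state encoding.  Media genes are external inputs and must
    have in-degree zero.
    """

    genes: tuple[str, ...]
    edges: tuple[tuple[str, str, int], ...]
    media_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene names")
        known = set(self.genes)
        seen: set[tuple[str, str]] = set()
        for src, tgt, sign in self.edges:
            if src not in known or tgt not in known:
                raise ValueError(f"edge ({src}, {tgt}) references unknown gene")
            if sign not in (-1, 1):
                raise ValueError(f"edge sign must be +1/-1, got {sign!r}")
            if (src, tgt) in seen:
                raise ValueError(f"duplicate edge ({src}, {tgt})")
            seen.add((src, tgt))
        for m in self.media_genes:
            if m not in known:
                raise ValueError(f"media gene {m!r} not in gene list")
            if any(tgt == m for _, tgt, _ in self.edges):
                raise ValueError(f"media gene {m!r} has regulators")

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def n_states(self) -> int:
        return 1 << len(self.genes)

    def bit(self, gene: str) -> int:
        """Bit position owned by ``gene``."""
        return self.genes.index(gene)

    def regulators(self, target: str) -> tuple[tuple[str, int], ...]:
        """(source, sign) pairs regulating ``target``, in edge order."""
        return tuple((s, sign) for s, t, sign in self.edges if t == target)

    def in_degree(self, target: str) -> int:
        return sum(1 for _, t, _ in self.edges if t == target)


@dataclass(frozen=True)
class ConstraintSet:
    """Named binary expression patterns that must appear as attractors.

    A pattern may be *full* (every gene assigned, defining a unique state
    index) or *partial* (only some genes pinned); a partial pattern
    matches any state agreeing on the assigned genes.
    """

    patterns: Mapping[str, Mapping[str, int]]
    media: tuple[str, ...] = ()

    def validate(self, grn: GRN) -> None:
        for name, pattern in self.patterns.items():
            for gene, value in pattern.items():
                if gene not in grn.genes:
                    raise ValueError(f"constraint {name!r} references unknown gene {gene!r}")
                if value not in (0, 1):
                    raise ValueError(f"constraint {name!r}: {gene}={value!r} not binary")
        for m in self.media:
            if m not in grn.genes:
                raise ValueError(f"constraint media gene {m!r} unknown")

    def state_index(self, name: str, grn: GRN) -> int:
        """Index of a full pattern; raises if the pattern is partial."""
        pattern = self.patterns[name]
        missing = set(grn.genes) - set(pattern)
        if missing:
            raise ValueError(f"constraint {name!r} is partial (missing {sorted(missing)})")
        return encode_state([pattern[g] for g in grn.genes])

    def matcher(self, name: str, grn: GRN):
        """Predicate on state indices: does the state agree with the pattern?"""
        pattern = self.patterns[name]
        bits = [(grn.bit(g), v) for g, v in pattern.items()]

        def match(s: int) -> bool:
            return all((s >> b) & 1 == v for b, v in bits)

        return match


def encode_state(bits: Sequence[int]) -> int:
    """Encode a gene-order bit vector ``(g_0, ..., g_{N-1})`` as an integer."""
    s = 0
    for i, g in enumerate(bits):
        if g not in (0, 1):
            raise ValueError(f"expression values must be 0/1, got {g!r} at position {i}")
        s |= g << i
    return s


def decode_state(s: int, n: int) -> tuple[int, ...]:
    """Inverse of :func:`encode_state`."""
    if not 0 <= s < (1 << n):
        raise ValueError(f"state index {s} out of range for {n} genes")
    return tuple((s >> i) & 1 for i in range(n))


def state_string(s: int, n: int) -> str:
    """Render a state index as a binary string, most-significant bit first."""
    return format(s, f"0{n}b")


def hamming_neighbors(s: int, n: int) -> list[int]:
    """The ``n`` state indices at Hamming distance 1 from ``s``, in bit order."""
    if not 0 <= s < (1 << n):
        raise ValueError(f"state index {s} out of range for {n} genes")
    return [s ^ (1 << i) for i in range(n)]


# ---------------------------------------------------------------------------
# File I/O
#
# Network file: TSV with a `source<TAB>target<TAB>sign` header, sign in
# {+1, -1, activate, repress}; `#` starts a comment; an optional
# `!genes: A B C` line fixes gene order (otherwise first-appearance
# order); an optional `!media: LIF` line flags input nodes.


def read_network(path: str | Path) -> GRN:
    path = Path(path)
    genes: list[str] = []
    declared: list[str] | None = None
    media: list[str] = []
    edges: list[tuple[str, str, int]] = []

    def note(gene: str) -> None:
        if gene not in genes:
            genes.append(gene)

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("!genes:"):
            declared = line[len("!genes:") :].split()
            continue
        if line.startswith("!media:"):
            media.extend(line[len("!media:") :].split())
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if parts == ["source", "target", "sign"]:
            continue
        if len(parts) != 3:
            raise NetworkParseError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
        src, tgt, token = parts
        if token not in _SIGN_TOKENS:
            raise NetworkParseError(f"{path}:{lineno}: unknown sign token {token!r}")
        note(src)
        note(tgt)
        edges.append((src, tgt, _SIGN_TOKENS[token]))

    if declared is not None:
        dangling = [g for g in genes if g not in declared]
        if dangling:
            raise NetworkParseError(f"{path}: genes {dangling} missing from !genes: header")
        genes = declared
    for m in media:
        note(m)
    try:
        return GRN(tuple(genes), tuple(edges), frozenset(media))
    except ValueError as exc:
        raise NetworkParseError(f"{path}: {exc}") from exc


def write_network(grn: GRN, path: str | Path) -> None:
    path = Path(path)
    lines = ["!genes: " + " ".join(grn.genes)]
    if grn.media_genes:
        lines.append("!media: " + " ".join(sorted(grn.media_genes)))
    lines.append("source\ttarget\tsign")
    for src, tgt, sign in grn.edges:
        lines.append(f"{src}\t{tgt}\t{'activate' if sign == 1 else 'repress'}")
    path.write_text("\n".join(lines) + "\n")


def read_constraints(path: str | Path) -> ConstraintSet:
    obj = json.loads(Path(path).read_text())
    if "attractors" not in obj:
        raise NetworkParseError(f"{path}: missing 'attractors' key")
    return ConstraintSet(
        {name: dict(pat) for name, pat in obj["attractors"].items()},
        tuple(obj.get("media", ())),
    )


def write_constraints(constraints: ConstraintSet, path: str | Path) -> None:
    obj = {
        "attractors": {k: dict(v) for k, v in constraints.patterns.items()},
        "media": list(constraints.media),
    }
    Path(path).write_text(json.dumps(obj, indent=1) + "\n")


def random_grn(
    n_genes: int,
    n_edges: int,
    repress_fraction: float = 0.3,
    seed: int | np.random.Generator = 0,
    allow_self_loops: bool = False,
) -> GRN:
    """Seeded random GRN generator for test inputs.

    Draws ``n_edges`` distinct ordered gene pairs uniformly (no self
    loops unless requested) and assigns each edge a repressive sign with
    probability ``repress_fraction``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = tuple(f"G{i}" for i in range(n_genes))
    pairs = [
        (a, b)
        for a in range(n_genes)
        for b in range(n_genes)
        if allow_self_loops or a != b
    ]
    if n_edges > len(pairs):
        raise ValueError(f"cannot place {n_edges} distinct edges among {len(pairs)} pairs")
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    edges = []
    for idx in sorted(int(i) for i in chosen):
        a, b = pairs[idx]
        sign = -1 if rng.random() < repress_fraction else 1
        edges.append((genes[a], genes[b], sign))
    return GRN(genes, tuple(edges))
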