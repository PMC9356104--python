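"""Discrete energy landscapes, attractors, basins, and configuration search.

For a network of ``N`` genes and a configuration of operators, every
binary cell state ``s`` receives an energy

    T(s) = sum over genes g of tau(a_g, i_g)

where ``a_g`` is g's expression in ``s`` and ``i_g`` the expressions of
its inputs.  The per-gene term rewards agreement between expression and
the net regulatory signal F(i_g):

    tau = L        if a_g equals the forced value f(F(i_g))
    tau = H        if it differs
    tau = (L+H)/2  if F(i_g) = 0 (no forcing)

With the defaults L = -1, H = +1 the neutral term is 0 and every energy
is an integer in [-N, +N]; T(s) = -N means every gene agrees with its
input signal.

Attractors are plateaus: maximal connected (Hamming-distance-1)
equal-energy sets none of whose members has a strictly lower-energy
neighbor.  A single-state plateau is an ordinary minimum; a multi-state
plateau is a degenerate attractor.  A state belongs to an attractor's
basin if a path of non-increasing-energy steps leads from it into the
attractor (flat steps are traversable).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .network import GRN, ConstraintSet, hamming_neighbors, state_string
from .operators import Operator, forcing
from .trees import (
    Configuration,
    evaluate_tree_all_states,
    exhaustive_search_space,
    sample_configuration,
    total_configs,
)

__all__ = [
    "EnergyLandscape",
    "Attractor",
    "SearchResult",
    "compute_landscape",
    "find_attractors",
    "basins",
    "satisfies_constraints",
    "search_configurations",
    "write_landscape",
    "attractor_report",
]


@dataclass(frozen=True)
class EnergyLandscape:
    """A vector of 2^N energies indexed by binary state."""

    energies: np.ndarray
    genes: tuple[str, ...]
    L: float = -1.0
    H: float = 1.0
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.genes)
        if len(self.energies) != 1 << n:
            raise ValueError(
                f"landscape over {n} genes needs {1 << n} energies, got {len(self.energies)}"
            )

    @property
    def n(self) -> int:
        return len(self.genes)

    @property
    def neutral(self) -> float:
        return (self.L + self.H) / 2

    def __getitem__(self, s: int) -> float:
        return float(self.energies[s])


@dataclass(frozen=True)
class Attractor:
    """A maximal equal-energy plateau with no lower Hamming neighbor."""

    states: frozenset[int]
    energy: float

    @property
    def degenerate(self) -> bool:
        return len(self.states) > 1

    @property
    def anchor(self) -> int:
        """Smallest member index; used for deterministic ordering/labels."""
        return min(self.states)


def compute_landscape(
    grn: GRN,
    config: Configuration,
    L: float = -1.0,
    H: float = 1.0,
) -> EnergyLandscape:
    """Energy of every state under ``config`` (vectorised over states)."""
    config.validate(grn)
    idx = np.arange(grn.n_states)
    T = np.zeros(grn.n_states, dtype=float)
    neutral = (L + H) / 2
    for i, gene in enumerate(grn.genes):
        F = evaluate_tree_all_states(config[gene], grn, gene)
        a = (idx >> i) & 1
        # f(F) for F = +1 is 1, for F = -1 is 0; neutral handled separately
        forced = (F + 1) // 2
        term = np.where(F == 0, neutral, np.where(a == forced, L, H))
        T += term
    if float(L).is_integer() and float(H).is_integer() and (L + H) % 2 == 0:
        T = T.astype(int).astype(float)
    return EnergyLandscape(
        T,
        grn.genes,
        L,
        H,
        provenance={"config": config.to_json()},
    )


def find_attractors(land: EnergyLandscape) -> list[Attractor]:
    """All attractors, ordered by (energy, smallest member index).

    Partitions the state space into maximal connected equal-energy
    plateaus and keeps those with no strictly lower-energy neighbor.
    """
    n = land.n
    E = land.energies
    n_states = 1 << n
    seen = np.zeros(n_states, dtype=bool)
    attractors: list[Attractor] = []
    for s0 in range(n_states):
        if seen[s0]:
            continue
        # flood-fill the equal-energy plateau containing s0
        plateau = {s0}
        stack = [s0]
        seen[s0] = True
        is_attractor = True
        while stack:
            s = stack.pop()
            for nb in hamming_neighbors(s, n):
                if E[nb] == E[s] and not seen[nb]:
                    seen[nb] = True
                    plateau.add(nb)
                    stack.append(nb)
                elif E[nb] < E[s]:
                    is_attractor = False
        if is_attractor:
            attractors.append(Attractor(frozenset(plateau), float(E[s0])))
    attractors.sort(key=lambda a: (a.energy, a.anchor))
    return attractors


def basins(
    land: EnergyLandscape,
    attractors: Sequence[Attractor],
    allow_flat: bool = True,
) -> dict[int, set[int]]:
    """Map each state to the set of attractor indices it can reach.

    A state reaches an attractor if a path exists in which every step
    moves to a neighbor of equal or lower energy (``allow_flat=True``,
    the default: flat segments are traversable in both directions) or of
    strictly lower energy (``allow_flat=False``; basins shrink).
    Computed by reverse BFS from the attractor states.
    """
    n = land.n
    E = land.energies
    reach: dict[int, set[int]] = {s: set() for s in range(1 << n)}
    for ai, att in enumerate(attractors):
        frontier = list(att.states)
        member = set(att.states)
        for s in member:
            reach[s].add(ai)
        while frontier:
            v = frontier.pop()
            for u in hamming_neighbors(v, n):
                if u in member:
                    continue
                ok = E[u] >= E[v] if allow_flat else E[u] > E[v]
                if ok:
                    member.add(u)
                    reach[u].add(ai)
                    frontier.append(u)
    return reach


def satisfies_constraints(
    attractors: Sequence[Attractor],
    constraints: ConstraintSet,
    grn: GRN,
) -> tuple[bool, dict]:
    """Check that every named constraint state lies in some attractor.

    Full patterns must be a member of an attractor (degenerate
    membership counts); partial patterns match any attractor containing
    a state that agrees on the assigned genes.  Surplus attractors are
    reported, never rejected: validity means the required states are
    present.
    """
    constraints.validate(grn)
    matched: dict[str, int | None] = {}
    used: set[int] = set()
    for name in constraints.patterns:
        match = constraints.matcher(name, grn)
        hit = None
        for ai, att in enumerate(attractors):
            if any(match(s) for s in att.states):
                hit = ai
                break
        matched[name] = hit
        if hit is not None:
            used.add(hit)
    ok = all(v is not None for v in matched.values())
    surplus = [ai for ai in range(len(attractors)) if ai not in used]
    report = {
        "satisfied": ok,
        "matched": matched,
        "surplus": surplus,
    }
    return ok, report


@dataclass
class SearchResult:
    """Outcome of a configuration search.

    ``prevalence[s]`` counts the landscapes in which state ``s`` was a
    member of some attractor (a state belongs to at most one attractor,
    so each landscape contributes at most 1 per state).
    """

    n_tested: int
    valid: list[Configuration]
    prevalence: np.ndarray
    mode: str

    def prevalence_fraction(self) -> np.ndarray:
        return self.prevalence / max(self.n_tested, 1)


def search_configurations(
    grn: GRN,
    ops: Sequence[Operator],
    constraints: ConstraintSet,
    mode: str = "exhaustive",
    budget: int | None = None,
    seed: int | None = None,
    guard: int = 10_000_000,
    force: bool = False,
    max_valid: int | None = None,
    progress: "callable | None" = None,
) -> SearchResult:
    """Test configurations against attractor constraints.

    ``mode="exhaustive"`` streams the full redundancy-free product space
    (guarded); ``mode="stochastic"`` samples ``budget`` random
    configurations from a seeded generator.  Streaming: memory is
    constant in the budget apart from the valid-configuration list
    (capped by ``max_valid`` if given).
    """
    if mode == "exhaustive":
        source: Iterator[Configuration] = exhaustive_search_space(
            grn, ops, guard=guard, force=force
        )
    elif mode == "stochastic":
        if seed is None or budget is None:
            raise ValueError("stochastic mode requires seed and budget")
        rng = np.random.default_rng(seed)

        def gen() -> Iterator[Configuration]:
            for _ in range(budget):
                yield sample_configuration(grn, ops, rng)

        source = gen()
    else:
        raise ValueError(f"unknown search mode {mode!r}")

    prevalence = np.zeros(grn.n_states, dtype=np.int64)
    valid: list[Configuration] = []
    n_tested = 0
    for config in source:
        land = compute_landscape(grn, config)
        attractors = find_attractors(land)
        for att in attractors:
            for s in att.states:
                prevalence[s] += 1
        ok, _ = satisfies_constraints(attractors, constraints, grn)
        if ok and (max_valid is None or len(valid) < max_valid):
            valid.append(config)
        n_tested += 1
        if progress is not None and n_tested % 10_000 == 0:
            progress(n_tested)
        if budget is not None and n_tested >= budget:
            break
    return SearchResult(n_tested, valid, prevalence, mode)


# ---------------------------------------------------------------------------
# Reports


def write_landscape(land: EnergyLandscape, path: str | Path) -> None:
    """Dump as TSV: ``index<TAB>bits(msb first)<TAB>energy``."""
    lines = ["index\tbits\tenergy"]
    for s in range(1 << land.n):
        lines.append(f"{s}\t{state_string(s, land.n)}\t{land[s]:g}")
    Path(path).write_text("\n".join(lines) + "\n")


def attractor_report(
    land: EnergyLandscape,
    attractors: Sequence[Attractor],
    constraints: ConstraintSet | None = None,
    grn: GRN | None = None,
) -> dict:
    """JSON-serialisable attractor summary, with constraint matching if given."""
    matched: Mapping[str, int | None] = {}
    surplus: Sequence[int] = list(range(len(attractors)))
    if constraints is not None and grn is not None:
        _, rep = satisfies_constraints(attractors, constraints, grn)
        matched = rep["matched"]
        surplus = rep["surplus"]
    inverse = {ai: name for name, ai in matched.items() if ai is not None}
    return {
        "attractors": [
            {
                "states": sorted(a.states),
                "bits": [state_string(s, land.n) for s in sorted(a.states)],
                "energy": a.energy,
                "degenerate": a.degenerate,
                "matched_constraint": inverse.get(ai),
            }
            for ai, a in enumerate(attractors)
        ],
        "surplus": list(surplus),
    }
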