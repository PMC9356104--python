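"""Boltzmann-weighted random walks ("marble simulations") on a landscape.

A marble at state ``s`` either hops to one of the N Hamming neighbors
or stays put.  Move probabilities are a softmax over energy changes:

    p(move to k) = exp(-beta * (E_k - E_s)) / Z

with the stay option contributing exp(0); ``beta`` is the noise level
(smaller beta = more noise = more uphill moves).  Frozen genes (e.g.
medium components that a cell cannot switch) are excluded before
normalisation.  A marble that stays in the same state for
``stop_repeats`` consecutive updates (default 3) has arrived; walks
exceeding ``max_steps`` are censored and counted under "Other".

Releasing many marbles from every state and recording which attractor
they arrive in maps out the relative strengths of the basins of
attraction.  Terminal states inside a degenerate attractor are pooled
into a single entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .landscape import Attractor, EnergyLandscape
from .network import hamming_neighbors

__all__ = [
    "MarbleConfig",
    "ProbabilityTable",
    "transition_probabilities",
    "step",
    "run_marble",
    "simulate_ensemble",
    "basin_strength_summary",
    "reprogramming_matrix",
    "media_transfer",
]


@dataclass(frozen=True)
class MarbleConfig:
    """Parameters of a marble ensemble.

    ``beta`` is the noise parameter (>= 0; larger = less noise).
    ``max_steps`` defaults to ``10 * N * stop_repeats``; walks hitting
    it are censored.  Each (initial state, replicate) pair gets its own
    RNG stream derived from ``seed`` by a counter scheme, so results are
    reproducible regardless of execution order.
    """

    beta: float = 1.0
    n_marbles: int = 100
    stop_repeats: int = 3
    max_steps: int | None = None
    seed: int = 0
    replicates: int = 3
    frozen_genes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.stop_repeats < 2:
            raise ValueError("stop_repeats must be at least 2")

    def resolved_max_steps(self, n: int) -> int:
        return self.max_steps if self.max_steps is not None else 10 * n * self.stop_repeats

    def rng_for(self, initial_state: int, replicate: int) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(replicate, initial_state))
        return np.random.default_rng(ss)


def transition_probabilities(
    land: EnergyLandscape,
    s: int,
    beta: float,
    frozen: Iterable[int] = (),
) -> np.ndarray:
    """Probabilities of the N neighbor moves (bit order) plus stay (last).

    Softmax with logits ``-beta * dE`` (stay has dE = 0); moves flipping
    a frozen gene get probability 0 before normalisation.
    """
    n = land.n
    frozen = set(frozen)
    dE = np.zeros(n + 1)
    for i, nb in enumerate(hamming_neighbors(s, n)):
        dE[i] = land[nb] - land[s]
    logits = -beta * dE
    logits -= logits.max()  # overflow guard; softmax is shift-invariant
    w = np.exp(logits)
    for i in frozen:
        w[i] = 0.0
    return w / w.sum()


def step(probs: np.ndarray, rng: np.random.Generator) -> int:
    """Inverse-CDF move selection: the smallest index whose cumulative
    probability exceeds a uniform draw r in [0, 1)."""
    r = rng.random()
    return int(np.searchsorted(np.cumsum(probs), r, side="right"))


class _WalkKernel:
    """Precomputed cumulative transition table for one (beta, frozen) pair."""

    def __init__(self, land: EnergyLandscape, beta: float, frozen: Iterable[int] = ()):
        self.land = land
        self.n = land.n
        n_states = 1 << self.n
        cum = np.empty((n_states, self.n + 1))
        for s in range(n_states):
            cum[s] = np.cumsum(transition_probabilities(land, s, beta, frozen))
        self.cum = cum
        self.neighbors = np.array(
            [hamming_neighbors(s, self.n) + [s] for s in range(n_states)]
        )

    def walk(
        self, start: int, rng: np.random.Generator, stop_repeats: int, max_steps: int
    ) -> tuple[int, int, bool]:
        state = start
        stays = 0
        for n_steps in range(1, max_steps + 1):
            move = int(np.searchsorted(self.cum[state], rng.random(), side="right"))
            nxt = int(self.neighbors[state, move])
            stays = stays + 1 if nxt == state else 0
            state = nxt
            if stays >= stop_repeats:
                return state, n_steps, False
        return state, max_steps, True


def run_marble(
    land: EnergyLandscape,
    start: int,
    config: MarbleConfig,
    rng: np.random.Generator,
) -> tuple[int, int, bool]:
    """Walk one marble; returns (final state, steps taken, censored flag)."""
    kernel = _WalkKernel(land, config.beta, config.frozen_genes)
    return kernel.walk(
        start, rng, config.stop_repeats, config.resolved_max_steps(land.n)
    )


@dataclass
class ProbabilityTable:
    """Per-initial-state probabilities of terminating in each attractor.

    ``table`` has a (initial, replicate) MultiIndex and one column per
    attractor label plus ``"Other"``; each row sums to 1.
    """

    table: pd.DataFrame
    labels: tuple[str, ...]

    def mean(self) -> pd.DataFrame:
        return self.table.groupby(level="initial", sort=False).mean()

    def std(self) -> pd.DataFrame:
        return self.table.groupby(level="initial", sort=False).std(ddof=1)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def _membership(attractors: Sequence[Attractor]) -> dict[int, int]:
    member: dict[int, int] = {}
    for ai, att in enumerate(attractors):
        for s in att.states:
            member[s] = ai
    return member


def default_labels(attractors: Sequence[Attractor]) -> tuple[str, ...]:
    return tuple(f"A{ai}" for ai in range(len(attractors)))


def simulate_ensemble(
    land: EnergyLandscape,
    attractors: Sequence[Attractor],
    config: MarbleConfig,
    initial_states: Sequence[int] | None = None,
    labels: Sequence[str] | None = None,
) -> ProbabilityTable:
    """Release ``n_marbles`` per initial state (times ``replicates``).

    Terminal states inside any attractor credit that attractor
    (degenerate members pooled); everything else, including censored
    walks, is credited to "Other".
    """
    labels = tuple(labels) if labels is not None else default_labels(attractors)
    if len(labels) != len(attractors):
        raise ValueError("one label per attractor required")
    if initial_states is None:
        initial_states = range(1 << land.n)
    member = _membership(attractors)
    kernel = _WalkKernel(land, config.beta, config.frozen_genes)
    max_steps = config.resolved_max_steps(land.n)

    rows = []
    index = []
    for rep in range(config.replicates):
        for s0 in initial_states:
            rng = config.rng_for(s0, rep)
            counts = np.zeros(len(attractors) + 1)
            for _ in range(config.n_marbles):
                final, _, censored = kernel.walk(
                    s0, rng, config.stop_repeats, max_steps
                )
                if not censored and final in member:
                    counts[member[final]] += 1
                else:
                    counts[-1] += 1
            rows.append(counts / config.n_marbles)
            index.append((s0, rep))
    table = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["initial", "replicate"]),
        columns=list(labels) + ["Other"],
    )
    return ProbabilityTable(table, labels)


@dataclass
class BasinStrengthSummary:
    """States ordered for a stacked basin-composition plot.

    States are segmented by dominating attractor (the most probable
    one; ties broken by label order) and ordered within each segment by
    the dominating probability, ascending.
    """

    order: list[int]
    segments: list[tuple[str, int]]  # (label, segment length) in plot order
    mean: pd.DataFrame  # reordered mean probabilities
    std: pd.DataFrame
    labels: tuple[str, ...]


def basin_strength_summary(ptable: ProbabilityTable) -> BasinStrengthSummary:
    mean = ptable.mean()
    std = ptable.std()
    att_cols = list(ptable.labels)
    dominating = mean[att_cols].to_numpy().argmax(axis=1)
    dom_prob = mean[att_cols].to_numpy().max(axis=1)
    states = np.asarray(mean.index)

    order: list[int] = []
    segments: list[tuple[str, int]] = []
    for ai, label in enumerate(att_cols):
        mask = dominating == ai
        if not mask.any():
            continue
        seg_states = states[mask]
        seg_order = seg_states[np.argsort(dom_prob[mask], kind="stable")]
        order.extend(int(s) for s in seg_order)
        segments.append((label, int(mask.sum())))
    return BasinStrengthSummary(
        order,
        segments,
        mean.loc[order],
        std.loc[order],
        ptable.labels,
    )


def reprogramming_matrix(
    land: EnergyLandscape,
    attractors: Sequence[Attractor],
    config: MarbleConfig,
    labels: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attractor-to-attractor transition probabilities (mean, std).

    Marbles start from each attractor; members of a degenerate attractor
    share the marble budget evenly.  Rows are row-stochastic.
    """
    labels = tuple(labels) if labels is not None else default_labels(attractors)
    member_states = [sorted(att.states) for att in attractors]
    ptable = simulate_ensemble(
        land,
        attractors,
        config,
        initial_states=sorted({s for states in member_states for s in states}),
        labels=labels,
    )
    mean_by_state = ptable.mean()
    std_by_state = ptable.std()
    mean_rows, std_rows = [], []
    for states in member_states:
        mean_rows.append(mean_by_state.loc[states].mean(axis=0))
        std_rows.append(std_by_state.loc[states].mean(axis=0))
    mean = pd.DataFrame(mean_rows, index=list(labels))
    std = pd.DataFrame(std_rows, index=list(labels))
    return mean, std


def media_transfer(
    land: EnergyLandscape,
    media_bits: Sequence[int],
    attractors: Sequence[Attractor],
    config: MarbleConfig,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate transferring each attractor population into each medium.

    ``media_bits`` are the bit positions of the medium genes.  For every
    assignment of medium values (each of the 2^m combinations) the
    initial attractor states are projected onto that medium (medium bits
    overwritten) and simulated with the medium genes frozen, i.e. on the
    disconnected sub-landscape belonging to that medium.  Returns mean
    probabilities indexed by (medium assignment, initial attractor).
    """
    labels = tuple(labels) if labels is not None else default_labels(attractors)
    media_bits = list(media_bits)
    frozen = tuple(sorted(set(config.frozen_genes) | set(media_bits)))
    rows = []
    index = []
    for combo in range(1 << len(media_bits)):
        mask = 0
        value = 0
        for j, b in enumerate(media_bits):
            mask |= 1 << b
            if (combo >> j) & 1:
                value |= 1 << b
        cfg = MarbleConfig(
            beta=config.beta,
            n_marbles=config.n_marbles,
            stop_repeats=config.stop_repeats,
            max_steps=config.max_steps,
            seed=config.seed,
            replicates=config.replicates,
            frozen_genes=frozen,
        )
        for ai, att in enumerate(attractors):
            starts = sorted({(s & ~mask) | value for s in att.states})
            ptable = simulate_ensemble(
                land, attractors, cfg, initial_states=starts, labels=labels
            )
            rows.append(ptable.mean().mean(axis=0))
            index.append((combo, labels[ai]))
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["medium", "initial"])
    )
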