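"""Packaged example networks and their attractor constraints.

Three fixtures ship with the package:

``"toy"``
    A synthetic 5-gene network (A..E, 9 signed edges) with two synthetic
    constraint states, 10110 (index 22) and 11101 (index 29).  The
    topology was chosen so that an exhaustive search over the
    {AND_HI, OR_HI} pair yields a valid landscape whose attractors are
    exactly the two constraint states plus one surplus state 01010 (10).

``"mef_ipsc"``
    The 14-node reprogramming network (13 transcription factors + the
    LIF medium input; 38 signed edges) transcribed from the published
    curated interaction table.  The constraint patterns (MEF, the
    2NG-/3NG- roadblock, iPSC) are synthetic binarization stand-ins:
    the original binarized expression profiles are shown only
    graphically, so these partial patterns pin the genes whose status
    the accompanying text makes explicit and leave the rest free.

``"pluripotency"``
    The 15-node naive-pluripotency maintenance network (12 transcription
    factors + LIF/CH/PD media inputs; 26 signed edges).  The edge list
    is reconstructed from the published network diagram; the in-degree
    sequence is exact (the six-operator configuration count is
    28179280429056).  Constraint patterns for the four media conditions
    are synthetic stand-ins in the same sense as above.
"""

from __future__ import annotations

from importlib import resources

from .network import GRN, ConstraintSet, read_constraints, read_network

__all__ = ["fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("toy", "mef_ipsc", "pluripotency")


def fixture(name: str) -> tuple[GRN, ConstraintSet]:
    """Load a packaged network and its constraint set by name."""
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
    base = resources.files(__package__) / "fixtures"
    with resources.as_file(base / f"{name}.tsv") as p:
        grn = read_network(p)
    with resources.as_file(base / f"{name}_constraints.json") as p:
        constraints = read_constraints(p)
    constraints.validate(grn)
    return grn, constraints
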