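#!/usr/bin/env python
"""Exhaustively test every two-operator configuration of the packaged
pluripotency network against its four media constraints.

For each of the three balanced operator pairs this computes roughly 10^6
landscapes of 32768 states each, so a full run takes hours on one CPU.
It is therefore a standalone script rather than part of the default test
suite.  With the packaged constraint patterns (synthetic stand-ins for
the experimental binarization) the expected outcome is that no
configuration satisfies all four constraints simultaneously.

Usage:  python scripts/exhaustive_pluripotency.py [--pair bar|underbar|maxmin]
"""

from __future__ import annotations

import argparse
import time

from logicscape.fixtures import fixture
from logicscape.landscape import search_configurations
from logicscape.operators import operator_set
from logicscape.trees import total_configs


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--pair", choices=["bar", "underbar", "maxmin"], default=None,
                        help="run a single pair instead of all three")
    args = parser.parse_args()
    grn, constraints = fixture("pluripotency")
    pairs = [args.pair] if args.pair else ["bar", "underbar", "maxmin"]
    for name in pairs:
        ops = operator_set(name)
        n = total_configs(grn, len(ops))
        print(f"pair {name}: {n} configurations to test")
        t0 = time.time()
        result = search_configurations(
            grn, ops, constraints, mode="exhaustive", force=True,
            progress=lambda k: print(f"  tested {k} ({time.time() - t0:.0f} s)"),
        )
        print(
            f"pair {name}: {result.n_tested} tested, {len(result.valid)} valid "
            f"({time.time() - t0:.0f} s)"
        )


if __name__ == "__main__":
    main()
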