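#!/usr/bin/env python
"""Calibration sweep for the sentence-parsing demo network.

The inter-node gains of the shipped demo are calibration artifacts; this
script sweeps the two quantities the parse outcome is most sensitive to
-- the asymmetric mutual-inhibition gains between the competing 'with'
modifiers and the contextual inhibition offset -- and prints the outcome
for each combination, so the shipped values can be re-derived or adapted.

Usage::

    python scripts/calibrate_demo.py [--seed 1]
"""

import argparse
from dataclasses import replace

from canmicro import sentence_demo, simulate_network
from canmicro.network import EdgeSpec


def with_inhibition_gains(spec, g_vo: float, g_ov: float):
    """Replace the modifier-competition gains (with_v -> with_o, with_o -> with_v)."""
    edges = []
    for e in spec.edges:
        if e.sign == "inhibitory" and {e.source, e.target} == {"with_v", "with_o"}:
            gain = g_vo if e.source == "with_v" else g_ov
            edges.append(EdgeSpec(e.source, e.target, e.sign, gain))
        else:
            edges.append(e)
    return replace(spec, edges=tuple(edges))


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    print(f"{'g_vo':>6} {'g_ov':>6} {'ctx':>6}  outcome")
    for g_vo in (5.0, 10.0, 20.0, 40.0):
        for g_ov in (0.0, 4.0, 10.0):
            for ctx in (0.0, 80.0, 150.0):
                spec, sched = sentence_demo(context="high", context_offset=ctx)
                spec = with_inhibition_gains(spec, g_vo, g_ov)
                trace = simulate_network(spec, sched, seed=args.seed)
                print(f"{g_vo:6.1f} {g_ov:6.1f} {ctx:6.1f}  "
                      f"{trace.outcome.value:16s} active={trace.active_nodes()}")


if __name__ == "__main__":
    main()
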