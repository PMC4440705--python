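"""Shared test utilities: a slow, readable reference SSA driver.

The driver below advances a cell with the object-level event executors and
`enumerate_channels`, independent of the compiled kernel, so the two
implementations can be cross-validated statistically.
"""

from __future__ import annotations

import numpy as np

from mitoqc import enumerate_channels
from mitoqc.engine import SimulationConfig, total_propensity
from mitoqc.events import (
    execute_fission,
    execute_fusion,
    execute_mitophagy,
    execute_replication,
)
from mitoqc.state import CellState


def pick_channel(channels, u: float):
    acc = 0.0
    for c in channels:
        acc += c.propensity
        if u < acc:
            return c
    return channels[-1]


def reference_ssa(state: CellState, cfg: SimulationConfig, seed: int):
    """Pure-python direct-method SSA; returns (samples, n_events).

    ``samples`` is a list of (time, n_mito, n_nucleoids, r_cell) tuples on
    the configured record grid.
    """
    rng = np.random.default_rng(seed)
    t = 0.0
    rec = list(cfg.record_grid)
    out = []
    n_events = 0

    def snap(time):
        ntot = state.n_nucleoids
        out.append(
            (time, state.n_mitochondria, ntot, state.M / ntot if ntot else np.nan)
        )

    while True:
        channels = enumerate_channels(state, cfg)
        A = total_propensity(channels)
        t_next = t + rng.exponential(1.0 / A) if A > 0 else np.inf
        while rec and rec[0] <= min(t_next, cfg.t_end):
            snap(rec.pop(0))
        if t_next >= cfg.t_end or not state.mitochondria:
            break
        t = t_next
        n_events += 1
        chosen = pick_channel(channels, rng.random() * A)
        by_id = {m.id: m for m in state.mitochondria}
        if chosen.kind == "replication":
            mid, identity = chosen.participants
            mito = by_id[mid]
            counts = [
                seg.M if identity == "M" else seg.W for seg in mito.chain
            ]
            probs = np.asarray(counts, dtype=float)
            seg_index = int(rng.choice(len(counts), p=probs / probs.sum()))
            execute_replication(state, mito, seg_index, identity == "M")
        elif chosen.kind == "mitophagy":
            execute_mitophagy(state, by_id[chosen.participants[0]])
        elif chosen.kind == "fusion":
            execute_fusion(
                state, by_id[chosen.participants[0]], by_id[chosen.participants[1]], rng
            )
        else:
            execute_fission(state, by_id[chosen.participants[0]], rng)
        state.check_invariants()
    return out, n_events
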