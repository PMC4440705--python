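"""State transitions for the four reaction classes.

These operate on the object-level :class:`~mitoqc.state.CellState` in place
(and return it, for chaining).  Random choices take a ``numpy.random.Generator``
so every transition is reproducible.  Effects on population bookkeeping:

==============  ====================  =========================
event           mitochondria count    nucleoid count
==============  ====================  =========================
replication     unchanged             +1
mitophagy       -1                    -(target's content)
fusion          -1                    conserved
fission         +1                    conserved
==============  ====================  =========================
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .state import CellState, Mitochondrion, Subcompartment

__all__ = [
    "EventRecord",
    "execute_mitophagy",
    "execute_replication",
    "execute_fusion",
    "execute_fission",
    "write_event_log",
]


@dataclass
class EventRecord:
    """One executed event: time, kind, participants, kind-specific payload."""

    t: float
    kind: str  # replication | mitophagy | fusion | fission
    participants: tuple[int, ...]
    detail: dict[str, Any] = field(default_factory=dict)

    def as_row(self) -> dict[str, Any]:
        return {
            "t": self.t,
            "kind": self.kind,
            "participants": ";".join(map(str, self.participants)),
            "detail": ";".join(f"{k}={v}" for k, v in sorted(self.detail.items())),
        }


def write_event_log(records, path) -> None:
    """Write an iterable of :class:`EventRecord` to a headered CSV file."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["t", "kind", "participants", "detail"])
        writer.writeheader()
        for rec in records:
            writer.writerow(rec.as_row())


def execute_mitophagy(state: CellState, target: Mitochondrion) -> CellState:
    """Remove ``target`` (whole chain, all nucleoids) from the population.

    Removing the last mitochondrion is permitted: the cell is flagged
    ``terminated_empty`` and must be excluded from further simulation.
    """
    state.mitochondria.remove(target)
    if not state.mitochondria:
        state.terminated_empty = True
    return state


def execute_replication(
    state: CellState, mito: Mitochondrion, seg_index: int, is_mutant: bool
) -> CellState:
    """Increment W or M of one subcompartment by 1 (faithful-nucleoid copy).

    The daughter nucleoid stays in its parent's subcompartment.
    """
    seg = mito.chain[seg_index]
    if is_mutant:
        if seg.M < 1:
            raise ValueError("no mutant nucleoid to replicate in this subcompartment")
        seg.M += 1
    else:
        if seg.W < 1:
            raise ValueError("no WT nucleoid to replicate in this subcompartment")
        seg.W += 1
    return state


def execute_fusion(
    state: CellState,
    mi: Mitochondrion,
    mj: Mitochondrion,
    rng: np.random.Generator,
) -> CellState:
    """Fuse a feasible pair: donor chain appended to the acceptor chain.

    Donor and acceptor roles are assigned by a fair coin flip.  Internal
    fission sites of both partners survive; one new site appears at the
    junction.  The fused mitochondrion keeps the acceptor's id and
    compartment; the donor is removed.
    """
    if mi is mj:
        raise ValueError("a mitochondrion cannot fuse with itself")
    if not state.graph.fusion_feasible(mi.compartment, mj.compartment):
        raise ValueError("fusion requires same or adjacent compartments")
    donor, acceptor = (mi, mj) if rng.random() < 0.5 else (mj, mi)
    acceptor.chain.extend(donor.chain)
    state.mitochondria.remove(donor)
    return state


def _binomial_exchange(
    left: Subcompartment, right: Subcompartment, left_rest: int, right_rest: int,
    rng: np.random.Generator,
) -> None:
    """Pool and redistribute two adjacent subcompartments, identity-blind.

    Each nucleoid of the pooled W and M contents lands left or right with
    probability 1/2 (Binomial splits drawn per identity).  Redrawn until
    both prospective daughters (including their untouched subcompartments,
    ``*_rest``) hold at least one nucleoid.
    """
    wp = left.W + right.W
    mp = left.M + right.M
    for _ in range(100000):
        wl = rng.binomial(wp, 0.5)
        ml = rng.binomial(mp, 0.5)
        if left_rest + wl + ml >= 1 and right_rest + (wp - wl) + (mp - ml) >= 1:
            left.W, left.M = int(wl), int(ml)
            right.W, right.M = int(wp - wl), int(mp - ml)
            return
    raise RuntimeError("binomial exchange failed to satisfy the >=1 constraint")


def execute_fission(
    state: CellState, mi: Mitochondrion, rng: np.random.Generator
) -> CellState:
    """Split a mitochondrion with >=2 nucleoids into two daughters.

    With internal fission sites, a site is chosen uniformly, the two
    subcompartments flanking it exchange their pooled contents by Binomial
    (p=1/2) draws, and the chain is cut there; each daughter keeps its
    sub-chain.  Without sites, the nucleoid total is cut at a uniform
    position (each daughter >=1) and mutant identities follow a
    hypergeometric draw (sampling without replacement).  One daughter stays
    in the original compartment; the other — chosen by a fair coin — is
    placed uniformly in the original or any neighboring compartment.
    """
    if mi.total < 2:
        raise ValueError("fission requires at least 2 nucleoids")
    if len(mi.chain) > 1:
        # restrict to viable sites: some exchange outcome must leave >=1
        # nucleoid on both sides (empty subcompartments can make a site
        # degenerate); the site is uniform over the viable ones
        viable = []
        for s in range(1, len(mi.chain)):
            lr = sum(seg.total for seg in mi.chain[: s - 1])
            rr = sum(seg.total for seg in mi.chain[s + 1 :])
            pool = mi.chain[s - 1].total + mi.chain[s].total
            lo = max(0, 1 - lr)
            hi = pool - max(0, 1 - rr)
            if hi >= lo:
                viable.append(s)
        site = int(viable[int(rng.integers(len(viable)))])  # cut between site-1 and site
        left_rest = sum(s.total for s in mi.chain[: site - 1])
        right_rest = sum(s.total for s in mi.chain[site + 1 :])
        _binomial_exchange(mi.chain[site - 1], mi.chain[site], left_rest, right_rest, rng)
        new_chain = mi.chain[site:]
        mi.chain = mi.chain[:site]
    else:
        total = mi.total
        k = int(rng.integers(1, total))  # nucleoids moving to the new daughter
        m_take = int(rng.hypergeometric(mi.M, mi.W, k)) if mi.M else 0
        seg = mi.chain[0]
        seg.W -= k - m_take
        seg.M -= m_take
        new_chain = [Subcompartment(W=k - m_take, M=m_take)]
    daughter = Mitochondrion(chain=new_chain, compartment=mi.compartment,
                             id=state.new_id())
    state.mitochondria.append(daughter)
    # Displacement: one daughter (fair coin) goes to a uniform choice among
    # the original compartment and its neighbors.
    displaced = mi if rng.random() < 0.5 else daughter
    options = [mi.compartment, *state.graph.neighbors[mi.compartment]]
    displaced.compartment = int(options[int(rng.integers(len(options)))])
    return state
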