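"""Cell state: mitochondria, their nucleoid contents, and summary metrics.

Each mitochondrion is an ordered chain of subcompartments.  A subcompartment
holds counts of wild-type (W) and mutant (M) mtDNA nucleoids and corresponds
to the nucleoid pool contributed by one parental mitochondrion in a past
fusion; the boundary between two consecutive subcompartments is a *fission
site*, the only place where the chain may be cut.  A mitochondrion with a
single subcompartment has no fission site.

Summary metrics follow the standard heteroplasmy bookkeeping:

* per-mitochondrion mutant fraction  ``R_M^mito = M_i / (W_i + M_i)``
* cell mutant fraction               ``R_M^cell = sum(M_i) / sum(W_i + M_i)``
* ``mean_mito_mutant_fraction``      unweighted mean of ``R_M^mito``
* ``cov_mito_mutant_fraction``       population SD of ``R_M^mito`` over its mean
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import CompartmentGraph, build_default_geometry

__all__ = [
    "Subcompartment",
    "Mitochondrion",
    "CellState",
    "cell_mutant_fraction",
    "mean_mito_mutant_fraction",
    "cov_mito_mutant_fraction",
]


@dataclass
class Subcompartment:
    """Nucleoid counts of one mitochondrial subcompartment."""

    W: int = 0
    M: int = 0

    def __post_init__(self) -> None:
        if self.W < 0 or self.M < 0:
            raise ValueError("nucleoid counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.W + self.M


@dataclass
class Mitochondrion:
    """An ordered chain of >=1 subcompartments residing in one compartment."""

    chain: list[Subcompartment]
    compartment: int
    id: int = -1

    def __post_init__(self) -> None:
        if len(self.chain) == 0:
            raise ValueError("a mitochondrion needs at least one subcompartment")
        if self.total < 1:
            raise ValueError("a mitochondrion must hold at least one nucleoid")

    @property
    def W(self) -> int:
        return sum(s.W for s in self.chain)

    @property
    def M(self) -> int:
        return sum(s.M for s in self.chain)

    @property
    def total(self) -> int:
        return self.W + self.M

    @property
    def n_fission_sites(self) -> int:
        return len(self.chain) - 1

    @property
    def mutant_fraction(self) -> float:
        """R_M^mito of this mitochondrion."""
        return self.M / self.total


@dataclass
class CellState:
    """Compartment graph plus the mitochondria population at time ``t`` (days)."""

    graph: CompartmentGraph = field(default_factory=build_default_geometry)
    mitochondria: list[Mitochondrion] = field(default_factory=list)
    t: float = 0.0
    terminated_empty: bool = False
    _next_id: int = 0

    def __post_init__(self) -> None:
        for m in self.mitochondria:
            if not 0 <= m.compartment < self.graph.n_compartments:
                raise ValueError("mitochondrion placed in an invalid compartment")
            if m.id < 0:
                m.id = self._next_id
                self._next_id += 1
        if self.mitochondria:
            self._next_id = max(self._next_id, max(m.id for m in self.mitochondria) + 1)

    def new_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    @property
    def n_mitochondria(self) -> int:
        return len(self.mitochondria)

    @property
    def W(self) -> int:
        return sum(m.W for m in self.mitochondria)

    @property
    def M(self) -> int:
        return sum(m.M for m in self.mitochondria)

    @property
    def n_nucleoids(self) -> int:
        return self.W + self.M

    def mutant_fractions(self) -> np.ndarray:
        """Array of R_M^mito over the population."""
        return np.array([m.mutant_fraction for m in self.mitochondria], dtype=float)

    def compartment_occupancy(self) -> np.ndarray:
        occ = np.zeros(self.graph.n_compartments, dtype=np.int64)
        for m in self.mitochondria:
            occ[m.compartment] += 1
        return occ

    def check_invariants(self) -> None:
        """Debug assertion: chain totals, compartment validity, metric bounds."""
        for m in self.mitochondria:
            assert m.total >= 1
            assert m.total == sum(s.W + s.M for s in m.chain)
            assert 0 <= m.compartment < self.graph.n_compartments
            assert 0.0 <= m.mutant_fraction <= 1.0
        assert int(self.compartment_occupancy().sum()) == self.n_mitochondria
        if self.n_mitochondria:
            assert 0.0 <= cell_mutant_fraction(self) <= 1.0

    # --- JSON checkpointing -------------------------------------------
    def to_json(self) -> str:
        doc = {
            "t": self.t,
            "n_compartments": self.graph.n_compartments,
            "neighbors": [list(nb) for nb in self.graph.neighbors],
            "terminated_empty": self.terminated_empty,
            "mitochondria": [
                {
                    "id": m.id,
                    "compartment": m.compartment,
                    "chain": [[s.W, s.M] for s in m.chain],
                }
                for m in self.mitochondria
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "CellState":
        doc = json.loads(text)
        graph = CompartmentGraph(
            doc["n_compartments"], tuple(tuple(nb) for nb in doc["neighbors"])
        )
        mitos = [
            Mitochondrion(
                chain=[Subcompartment(w, m) for w, m in rec["chain"]],
                compartment=rec["compartment"],
                id=rec["id"],
            )
            for rec in doc["mitochondria"]
        ]
        return cls(
            graph=graph,
            mitochondria=mitos,
            t=doc["t"],
            terminated_empty=doc.get("terminated_empty", False),
        )


def cell_mutant_fraction(state: CellState) -> float:
    """R_M^cell: mutant share of all nucleoids in the cell."""
    total = state.n_nucleoids
    if total < 1:
        raise ValueError("cell mutant fraction undefined for an empty population")
    return state.M / total


def mean_mito_mutant_fraction(state: CellState) -> float:
    """Unweighted mean of R_M^mito over the mitochondria population."""
    if state.n_mitochondria < 1:
        raise ValueError("mean mitochondrial mutant fraction needs >=1 mitochondrion")
    return float(state.mutant_fractions().mean())


def cov_mito_mutant_fraction(state: CellState) -> float:
    """Coefficient of variation of R_M^mito (population SD / mean).

    Returns ``nan`` when the mean is zero (homoplasmic wild-type cell); such
    cells are excluded from ensemble averages of the COV.  Requires at least
    two mitochondria.
    """
    if state.n_mitochondria < 2:
        raise ValueError("COV of R_M^mito needs >=2 mitochondria")
    r = state.mutant_fractions()
    mean = r.mean()
    if mean == 0.0:
        return float("nan")
    return float(r.std(ddof=0) / mean)
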