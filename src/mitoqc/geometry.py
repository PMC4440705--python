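"""Compartment geometry of the simulated cell.

The cell interior is discretized into a small number of compartments whose
width matches the range of directed mitochondrial movement (~3 um in a 20 um
cell, giving 16 compartments by default).  Mitochondria live in compartments;
fusion is only feasible between mitochondria in the same or adjacent
compartments, and a fission daughter may be displaced into a neighboring
compartment.  Only the adjacency structure matters to the dynamics — metric
coordinates are never used — so the geometry is just a small symmetric graph.

The default layout is a ring of 16 compartments in which every compartment is
adjacent to its two nearest and two next-nearest ring neighbors (degree 4),
approximating the local connectivity of a 2D patchwork partition of a disc.
Alternative layouts can be supplied anywhere a :class:`CompartmentGraph` is
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CompartmentGraph", "build_default_geometry"]

DEFAULT_N_COMPARTMENTS = 16


@dataclass(frozen=True)
class CompartmentGraph:
    """Symmetric, irreflexive adjacency between cell compartments.

    Parameters
    ----------
    n_compartments:
        Number of compartments (graph nodes), indexed ``0..n-1``.
    neighbors:
        Tuple of sorted tuples; ``neighbors[c]`` lists the compartments
        adjacent to ``c``.  Must be symmetric, irreflexive, and leave no
        compartment isolated.
    """

    n_compartments: int
    neighbors: tuple[tuple[int, ...], ...] = field(repr=False)

    def __post_init__(self) -> None:
        n = self.n_compartments
        if n < 2:
            raise ValueError("a cell needs at least 2 compartments")
        if len(self.neighbors) != n:
            raise ValueError("neighbor table length must equal n_compartments")
        for c, nbrs in enumerate(self.neighbors):
            if len(nbrs) == 0:
                raise ValueError(f"compartment {c} has no neighbors")
            for d in nbrs:
                if d == c:
                    raise ValueError("adjacency must be irreflexive")
                if not 0 <= d < n:
                    raise ValueError(f"neighbor index {d} out of range")
                if c not in self.neighbors[d]:
                    raise ValueError("adjacency must be symmetric")

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=np.int64)

    def are_adjacent(self, c: int, d: int) -> bool:
        return d in self.neighbors[c]

    def fusion_feasible(self, c: int, d: int) -> bool:
        """Whether mitochondria in compartments ``c`` and ``d`` may fuse."""
        return c == d or self.are_adjacent(c, d)

    def edges(self) -> list[tuple[int, int]]:
        """Undirected edge list with ``c < d``."""
        out = []
        for c, nbrs in enumerate(self.neighbors):
            for d in nbrs:
                if c < d:
                    out.append((c, d))
        return out

    # --- array views consumed by the simulation core -------------------
    def neighbor_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(nbr, deg)`` padded arrays for the compiled core."""
        deg = self.degrees
        nbr = np.full((self.n_compartments, int(deg.max())), -1, dtype=np.int64)
        for c, nbrs in enumerate(self.neighbors):
            nbr[c, : len(nbrs)] = nbrs
        return nbr, deg

    def edge_array(self) -> np.ndarray:
        e = self.edges()
        return np.array(e, dtype=np.int64).reshape(len(e), 2)

    @classmethod
    def ring(cls, n_compartments: int, reach: int = 2) -> "CompartmentGraph":
        """Ring of ``n_compartments``, each adjacent to ring neighbors within
        ``reach`` steps (``reach=2`` gives the default degree-4 layout)."""
        if n_compartments < 2:
            raise ValueError("a cell needs at least 2 compartments")
        nbrs = []
        for c in range(n_compartments):
            s = set()
            for k in range(1, reach + 1):
                s.add((c + k) % n_compartments)
                s.add((c - k) % n_compartments)
            s.discard(c)
            nbrs.append(tuple(sorted(s)))
        return cls(n_compartments, tuple(nbrs))


def build_default_geometry(n_compartments: int = DEFAULT_N_COMPARTMENTS) -> CompartmentGraph:
    """Default compartment layout: ring with next-nearest-neighbor adjacency.

    Deterministic for a fixed ``n_compartments``.  Raises ``ValueError`` for
    ``n_compartments < 2``.
    """
    return CompartmentGraph.ring(n_compartments, reach=2)
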