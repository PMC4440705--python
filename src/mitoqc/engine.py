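"""Exact stochastic simulation (Gillespie direct method) of one cell.

`run_cell` advances a :class:`~mitoqc.state.CellState` under the four
reaction classes (replication, mitophagy, fusion, fission) with exponential
waiting times and propensity-proportional channel choice, recording per-cell
summary statistics on a sampling grid.  The hot loop lives in the compiled
kernel (:mod:`mitoqc._core`); this module owns configuration, array
conversion, reproducible seeding, and the object-level channel enumeration
used by tests and diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from . import _core
from .geometry import CompartmentGraph
from .kinetics import (
    QCParams,
    fission_propensity,
    fusion_pair_propensity,
    mitophagy_propensity,
    replication_propensity_per_nucleoid,
)
from .state import CellState, Mitochondrion, Subcompartment, cell_mutant_fraction, \
    mean_mito_mutant_fraction

__all__ = [
    "ALL_CHANNELS",
    "SimulationConfig",
    "Trajectory",
    "EpisodeLog",
    "Channel",
    "enumerate_channels",
    "run_cell",
    "child_seed",
]

ALL_CHANNELS = frozenset({"replication", "mitophagy", "fusion", "fission"})


def child_seed(master_seed: int, *indices: int) -> int:
    """Deterministic child seed from a master seed and counter indices.

    Counter-based (numpy ``SeedSequence``) so ensembles are reproducible
    regardless of execution order; the result fits in a signed 31-bit int.
    """
    ss = np.random.SeedSequence([int(master_seed), *map(int, indices)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass(frozen=True)
class SimulationConfig:
    """One cell-simulation run: horizon, sampling grid, seed, parameters."""

    t_end: float
    params: QCParams = field(default_factory=QCParams)
    seed: int = 0
    record_grid: Optional[np.ndarray] = None  # default: daily, 0..t_end
    enabled_channels: frozenset[str] = ALL_CHANNELS
    track_episodes: bool = False
    rich_threshold: float = 0.9
    #: Divergence guard: when retrograde-amplified replication of a mutant-
    #: dominated cell turns supercritical the copy number grows without
    #: bound; past this cap the cell is flagged saturated and its statistics
    #: are carried forward (it is effectively fixed for the mutant).
    max_nucleoids: int = 3200

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        unknown = set(self.enabled_channels) - ALL_CHANNELS
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        grid = self.record_grid
        if grid is None:
            grid = np.arange(0.0, self.t_end + 1e-9, 1.0)
            object.__setattr__(self, "record_grid", grid)
        grid = np.asarray(grid, dtype=float)
        if np.any(np.diff(grid) < 0) or grid[0] < 0 or grid[-1] > self.t_end + 1e-9:
            raise ValueError("record_grid must be sorted within [0, t_end]")
        object.__setattr__(self, "record_grid", grid)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass
class EpisodeLog:
    """Mutant-rich episode summary of one run."""

    threshold: float
    n_starts: int
    durations: np.ndarray  # completed + censored episode durations (days)
    duration_sum: float
    n_censored: int
    mito_days: float  # integral of the mitochondria count over time


@dataclass
class Trajectory:
    """Time-sampled per-cell statistics plus the final state."""

    times: np.ndarray
    r_cell: np.ndarray  # R_M^cell
    n_mito: np.ndarray
    n_nucleoids: np.ndarray
    rbar_mito: np.ndarray  # mean of R_M^mito
    cov: np.ndarray  # COV of R_M^mito (NaN where undefined)
    final_state: CellState
    terminated_empty: bool = False
    saturated: bool = False
    n_events: int = 0
    episodes: Optional[EpisodeLog] = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "r_cell": self.r_cell,
                "n_mito": self.n_mito,
                "n_nucleoid": self.n_nucleoids,
                "rbar_mito": self.rbar_mito,
                "cov": self.cov,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# object-level channel enumeration (reference / diagnostics)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Channel:
    """One reaction channel: kind, participant mitochondrion ids, propensity.

    Replication channels are aggregated per (mitochondrion, identity); their
    propensity is the nucleoid count times the per-nucleoid rate, which is
    equivalent to one channel per nucleoid.
    """

    kind: str
    participants: tuple
    propensity: float


def enumerate_channels(state: CellState, cfg: SimulationConfig) -> list[Channel]:
    """All reaction channels of ``state`` with their propensities."""
    p = cfg.params
    on = cfg.enabled_channels
    channels: list[Channel] = []
    mitos = state.mitochondria
    if "replication" in on and mitos:
        rbar = (
            cell_mutant_fraction(state)
            if p.retrograde_uses_cell_fraction
            else mean_mito_mutant_fraction(state)
        )
        w_rate = replication_propensity_per_nucleoid(False, rbar, p)
        m_rate = replication_propensity_per_nucleoid(True, rbar, p)
        for m in mitos:
            if m.W:
                channels.append(Channel("replication", (m.id, "W"), m.W * w_rate))
            if m.M:
                channels.append(Channel("replication", (m.id, "M"), m.M * m_rate))
    if "mitophagy" in on:
        for m in mitos:
            channels.append(
                Channel("mitophagy", (m.id,), mitophagy_propensity(m.mutant_fraction, p))
            )
    if "fission" in on:
        for m in mitos:
            if m.total >= 2:
                channels.append(Channel("fission", (m.id,), fission_propensity(m, p)))
    if "fusion" in on:
        for a in range(len(mitos)):
            for b in range(a + 1, len(mitos)):
                mi, mj = mitos[a], mitos[b]
                if state.graph.fusion_feasible(mi.compartment, mj.compartment):
                    channels.append(
                        Channel("fusion", (mi.id, mj.id), fusion_pair_propensity(mi, mj, p))
                    )
    return channels


def total_propensity(channels: Iterable[Channel]) -> float:
    return float(sum(c.propensity for c in channels))


# ---------------------------------------------------------------------------
# array conversion and the compiled-core driver
# ---------------------------------------------------------------------------

def _params_vector(p: QCParams) -> np.ndarray:
    return np.array(
        [
            p.k_D,
            p.r_D_max,
            p.K_D**p.m,
            p.m,
            p.a_R0_per_nucleoid,
            p.r_R_max,
            p.K_R**p.m,
            p.k_R,
            p.a_fusion_eff,
            p.r_fusion_max,
            p.K_fusion**p.m,
            p.V_F_eff,
            p.K_F**p.n,
            p.n,
        ],
        dtype=float,
    )


def _flags_vector(cfg: SimulationConfig) -> np.ndarray:
    on = cfg.enabled_channels
    return np.array(
        [
            int("replication" in on),
            int("mitophagy" in on),
            int("fusion" in on),
            int("fission" in on),
            int(cfg.params.retrograde_uses_cell_fraction),
            int(cfg.track_episodes),
        ],
        dtype=np.int64,
    )


def state_to_arrays(state: CellState, cap_m: int, cap_s: int):
    n = state.n_mitochondria
    if n > cap_m:
        raise ValueError("mitochondria capacity too small for the state")
    segW = np.zeros((cap_m, cap_s), dtype=np.int64)
    segM = np.zeros((cap_m, cap_s), dtype=np.int64)
    nseg = np.zeros(cap_m, dtype=np.int64)
    comp = np.zeros(cap_m, dtype=np.int64)
    for i, m in enumerate(state.mitochondria):
        if len(m.chain) > cap_s:
            raise ValueError("chain capacity too small for the state")
        nseg[i] = len(m.chain)
        comp[i] = m.compartment
        for k, seg in enumerate(m.chain):
            segW[i, k] = seg.W
            segM[i, k] = seg.M
    return segW, segM, nseg, comp, n


def arrays_to_state(
    graph: CompartmentGraph, segW, segM, nseg, comp, n: int, t: float,
    terminated_empty: bool = False,
) -> CellState:
    mitos = []
    for i in range(n):
        chain = [
            Subcompartment(int(segW[i, k]), int(segM[i, k])) for k in range(nseg[i])
        ]
        mitos.append(Mitochondrion(chain=chain, compartment=int(comp[i]), id=i))
    return CellState(graph=graph, mitochondria=mitos, t=t,
                     terminated_empty=terminated_empty)


def _initial_capacity(state: CellState) -> tuple[int, int]:
    # the driver doubles and reruns on overflow, so start modest; the
    # mitochondria count is bounded by the nucleoid count
    cap_m = max(4 * state.n_mitochondria + 64, 1024)
    return cap_m, 64


def run_cell(initial: CellState, cfg: SimulationConfig) -> Trajectory:
    """Run the exact SSA from ``initial`` until ``cfg.t_end``.

    Reproducible: the same initial state, configuration and seed give a
    bit-identical trajectory.  If the last mitochondrion is removed the cell
    is flagged terminated-empty and the remaining samples hold NaN fractions.
    """
    p = cfg.params
    rec = np.asarray(cfg.record_grid, dtype=float)
    P = _params_vector(p)
    flags = _flags_vector(cfg)
    nbr, deg = initial.graph.neighbor_arrays()
    edges = initial.graph.edge_array()
    cap_m, cap_s = _initial_capacity(initial)

    while True:
        segW, segM, nseg, comp, n0 = state_to_arrays(initial, cap_m, cap_s)
        nrec = rec.shape[0]
        snap_r = np.empty(nrec)
        snap_nm = np.empty(nrec)
        snap_nuc = np.empty(nrec)
        snap_rbar = np.empty(nrec)
        snap_cov = np.empty(nrec)
        ep_durs = np.zeros(8192)
        out = np.zeros(8)
        status = _core.run_ssa(
            int(cfg.seed) & 0x7FFFFFFF,
            0.0,  # run-relative clock; the final state carries the offset
            float(cfg.t_end),
            rec,
            P,
            flags,
            float(cfg.rich_threshold),
            int(cfg.max_nucleoids),
            nbr,
            deg,
            edges,
            segW,
            segM,
            nseg,
            comp,
            n0,
            snap_r,
            snap_nm,
            snap_nuc,
            snap_rbar,
            snap_cov,
            ep_durs,
            out,
        )
        if status == _core.STATUS_CAP_MITO:
            cap_m *= 2
            continue
        if status == _core.STATUS_CAP_SEG:
            cap_s *= 2
            continue
        break

    n_final = int(out[_core.O_N_FINAL])
    terminated = status == _core.STATUS_EMPTY
    saturated = status == _core.STATUS_SATURATED
    final = arrays_to_state(
        initial.graph, segW, segM, nseg, comp, n_final,
        float(initial.t) + float(cfg.t_end),
        terminated_empty=terminated,
    )
    episodes = None
    if cfg.track_episodes:
        n_eps = int(out[_core.O_EP_COUNT])
        episodes = EpisodeLog(
            threshold=cfg.rich_threshold,
            n_starts=int(out[_core.O_EP_STARTS]),
            durations=ep_durs[: min(n_eps, ep_durs.shape[0])].copy(),
            duration_sum=float(out[_core.O_EP_DURSUM]),
            n_censored=int(out[_core.O_EP_CENSORED]),
            mito_days=float(out[_core.O_MITO_DAYS]),
        )
    return Trajectory(
        times=rec.copy(),
        r_cell=snap_r,
        n_mito=snap_nm,
        n_nucleoids=snap_nuc,
        rbar_mito=snap_rbar,
        cov=snap_cov,
        final_state=final,
        terminated_empty=terminated,
        saturated=saturated,
        n_events=int(out[_core.O_N_EVENTS]),
        episodes=episodes,
    )
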