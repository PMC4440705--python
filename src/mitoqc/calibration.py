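"""Premixing protocol and mixing-time calibration.

Every experiment starts from a *premixed* cell: 2 mitochondria per
compartment (32 in the default geometry), 10 wild-type nucleoids each, run
under fusion-fission alone for 50 days so that the nucleoid-per-mitochondrion
distribution and the spatial arrangement forget the (unknown) initial
condition.  Fusion-fission conserves nucleoids, so premixing ends with
exactly 320 nucleoids.

The *mixing time constant* τ quantifies fusion-fission frequency: starting
from a premixed cell with half the nucleoids relabeled as mutant (labels
only — no selectivity, no turnover), τ is the time for the ensemble-mean
coefficient of variation of the per-mitochondrion mutant fraction to complete
63.2% of its approach to the steady-state plateau.  The nominal fusion and
fission rates give τ = 7.5 days; scaling both rates by a common factor
``ff_scale`` rescales time, so τ(ff_scale) = 7.5 / ff_scale and
`scale_for_tau` is exact inversion rather than a search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import SimulationConfig, Trajectory, child_seed, run_cell
from .geometry import CompartmentGraph, build_default_geometry
from .kinetics import QCParams, TAU_NOMINAL
from .state import CellState, Mitochondrion, Subcompartment

__all__ = [
    "initial_premix_state",
    "premix_horizon",
    "premix",
    "MixingCurve",
    "estimate_mixing_time",
    "scale_for_tau",
    "relabel_block",
    "relabel_random_nucleoid",
]

FUSION_FISSION_ONLY = frozenset({"fusion", "fission"})
#: Mixing completion level defining tau (1 - 1/e).
TAU_LEVEL = 0.632


def initial_premix_state(
    graph: CompartmentGraph | None = None,
    mitos_per_compartment: int = 2,
    nucleoids_per_mito: int = 10,
) -> CellState:
    """Pre-premixing configuration: uniform WT mitochondria, two per compartment."""
    graph = graph or build_default_geometry()
    mitos = []
    for c in range(graph.n_compartments):
        for _ in range(mitos_per_compartment):
            mitos.append(
                Mitochondrion(
                    chain=[Subcompartment(W=nucleoids_per_mito, M=0)], compartment=c
                )
            )
    return CellState(graph=graph, mitochondria=mitos, t=0.0)


def premix_horizon(params: QCParams) -> float:
    """Premixing duration in days.

    50 days suffices for every mixing time up to τ = 30 days; slower presets
    extend the horizon proportionally so the distribution still reaches
    steady state.
    """
    tau = TAU_NOMINAL / params.ff_scale
    return 50.0 if tau <= 30.0 else 50.0 * tau / 30.0


def premix(
    params: QCParams,
    seed: int,
    graph: CompartmentGraph | None = None,
    horizon: float | None = None,
) -> CellState:
    """Fusion-fission-only burn-in from the uniform initial configuration."""
    initial = initial_premix_state(graph)
    t_end = premix_horizon(params) if horizon is None else float(horizon)
    cfg = SimulationConfig(
        t_end=t_end,
        params=params,
        seed=seed,
        record_grid=np.array([0.0, t_end]),
        enabled_channels=FUSION_FISSION_ONLY,
    )
    traj = run_cell(initial, cfg)
    return traj.final_state


def relabel_block(state: CellState, n_mutant: int | None = None) -> CellState:
    """Relabel nucleoids as mutant by whole mitochondria until the quota.

    Walks the population in storage order converting W to M wholesale; the
    remainder is split inside the next mitochondrion.  Block labeling
    maximizes the initial between-mitochondria contrast, which is what the
    mixing-time protocol measures.  Labels are identities only; selectivity
    must be disabled by the caller's parameter choice.
    """
    if n_mutant is None:
        n_mutant = state.n_nucleoids // 2
    remaining = n_mutant
    for m in state.mitochondria:
        if remaining <= 0:
            break
        for seg in m.chain:
            take = min(seg.W, remaining)
            seg.W -= take
            seg.M += take
            remaining -= take
            if remaining <= 0:
                break
    if remaining > 0:
        raise ValueError("not enough wild-type nucleoids to relabel")
    return state


def relabel_random_nucleoid(state: CellState, rng: np.random.Generator,
                            n_mutant: int = 1) -> CellState:
    """Relabel ``n_mutant`` uniformly chosen WT nucleoids as mutant."""
    for _ in range(n_mutant):
        total_w = state.W
        if total_w < 1:
            raise ValueError("no wild-type nucleoid left to relabel")
        target = int(rng.integers(total_w))
        acc = 0
        for m in state.mitochondria:
            for seg in m.chain:
                acc += seg.W
                if target < acc:
                    seg.W -= 1
                    seg.M += 1
                    break
            else:
                continue
            break
    return state


@dataclass
class MixingCurve:
    """Ensemble-mean COV of R_M^mito during a label-mixing run."""

    times: np.ndarray
    mean_cov: np.ndarray
    plateau: float

    @property
    def scaled_percent(self) -> np.ndarray:
        """Curve rescaled so t=0 maps to 0% and the plateau to -100%."""
        c0 = self.mean_cov[0]
        return -100.0 * (c0 - self.mean_cov) / (c0 - self.plateau)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "mean_cov": self.mean_cov,
                "scaled_percent": self.scaled_percent,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass
class MixingTimeResult:
    tau: float
    curve: MixingCurve
    n_cells: int


def estimate_mixing_time(
    params: QCParams,
    n_cells: int = 500,
    seed: int = 0,
    horizon: float | None = None,
    record_dt: float = 0.25,
    plateau_window: float = 0.2,
    random_labels: bool = False,
) -> MixingTimeResult:
    """Estimate the mixing time constant τ for the given fusion-fission rates.

    Per cell: premix, relabel half the nucleoids as mutant (block labeling
    by whole mitochondria by default, uniformly random labels behind the
    ``random_labels`` flag), then run fusion-fission alone and record the COV
    of R_M^mito.  The ensemble-mean COV decays to a plateau (estimated as
    the mean over the trailing ``plateau_window`` fraction of the horizon);
    τ is the first time the curve completes 63.2% of the total change,
    located by linear interpolation.

    Raises ``RuntimeError`` if the curve has not plateaued in the horizon.
    """
    if n_cells < 2:
        raise ValueError("mixing-time estimation needs >= 2 cells")
    # selectivity and turnover are irrelevant to labels; force them off so
    # the M-labels behave identically to W
    p = params.with_(r_fusion_max=0.0)
    if horizon is None:
        horizon = 8.0 * TAU_NOMINAL / p.ff_scale
    grid = np.arange(0.0, horizon + 1e-9, record_dt)
    covs = np.empty((n_cells, grid.shape[0]))
    for k in range(n_cells):
        cell = premix(p, seed=child_seed(seed, k, 0))
        relabel_block(cell) if not random_labels else _relabel_random_half(
            cell, np.random.default_rng(child_seed(seed, k, 1))
        )
        cfg = SimulationConfig(
            t_end=horizon,
            params=p,
            seed=child_seed(seed, k, 2),
            record_grid=grid,
            enabled_channels=FUSION_FISSION_ONLY,
        )
        covs[k] = run_cell(cell, cfg).cov
    mean_cov = np.nanmean(covs, axis=0)

    tail = mean_cov[grid >= horizon * (1.0 - plateau_window)]
    plateau = float(tail.mean())
    c0 = float(mean_cov[0])
    change = c0 - plateau
    if change <= 0:
        raise RuntimeError("mixing curve shows no decay; check the protocol")
    # plateau sanity: the trailing half of the tail window must agree with
    # the full tail to within 5% of the total change
    tail2 = mean_cov[grid >= horizon * (1.0 - plateau_window / 2)]
    if abs(float(tail2.mean()) - plateau) > 0.05 * change:
        raise RuntimeError(
            "mixing curve has not reached steady state; increase the horizon"
        )
    target = c0 - TAU_LEVEL * change
    below = np.nonzero(mean_cov <= target)[0]
    if below.size == 0:
        raise RuntimeError(
            "mixing curve never completes 63.2% of its change; increase the horizon"
        )
    j = int(below[0])
    if j == 0:
        tau = float(grid[0])
    else:
        t1, t2 = grid[j - 1], grid[j]
        y1, y2 = mean_cov[j - 1], mean_cov[j]
        tau = float(t1 + (target - y1) * (t2 - t1) / (y2 - y1))
    return MixingTimeResult(
        tau=tau, curve=MixingCurve(grid, mean_cov, plateau), n_cells=n_cells
    )


def _relabel_random_half(state: CellState, rng: np.random.Generator) -> CellState:
    return relabel_random_nucleoid(state, rng, n_mutant=state.n_nucleoids // 2)


def scale_for_tau(target_tau: float, params: QCParams) -> QCParams:
    """Parameters realizing the requested mixing time constant.

    Fusion and fission frequencies scale together (``ff_scale``), preserving
    their ratio, with the nominal anchor τ(ff_scale=1) = 7.5 days.
    """
    if target_tau <= 0:
        raise ValueError("the mixing time constant must be positive")
    return params.with_(ff_scale=TAU_NOMINAL / target_tau)
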