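"""Ensemble scenario runner and mutant-rich episode statistics.

A *scenario* is a clonal-expansion experiment: per cell, premix under
fusion-fission alone, relabel one uniformly chosen nucleoid as the de novo
mutant (a relabeling, so the 320-nucleoid total is preserved at t=0), then
run the full quality-control model and aggregate the cell mutant fraction
R_M^cell over the ensemble.  Presets cover the standard perturbation panels:
mixing time τ ∈ {7.5, 30, 120} days, replicative advantage (k_R = 2),
non-selective fusion (r_fusion_max = 0), high mitophagy selectivity
(r_D_max = 199), absolute fusion selectivity (r_fusion_max = 1), and the
aged-cell setting with both selectivities halved.

`track_mutant_rich_episodes` measures the transient appearance of
mitochondria whose mutant fraction exceeds a high threshold (0.9 by
default), under fusion-fission alone with non-selective fusion: the
per-mitochondrion occurrence rate of such episodes and their mean lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import FUSION_FISSION_ONLY, premix, relabel_random_nucleoid, \
    scale_for_tau
from .engine import ALL_CHANNELS, SimulationConfig, child_seed, run_cell
from .kinetics import QCParams

__all__ = [
    "ScenarioSpec",
    "EnsembleResult",
    "EpisodeStats",
    "run_scenario",
    "scenario_presets",
    "track_mutant_rich_episodes",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One named ensemble experiment."""

    name: str
    params: QCParams
    n_cells: int = 500
    t_end: float = 300.0
    introduce_mutant: bool = True
    channels: frozenset[str] = ALL_CHANNELS
    record_dt: float = 1.0

    def with_(self, **kwargs) -> "ScenarioSpec":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class EnsembleResult:
    """Ensemble statistics of R_M^cell on the sampling grid."""

    spec: ScenarioSpec
    times: np.ndarray
    mean_r_cell: np.ndarray  # R̄_M^cell(t), mean over cells
    sd_r_cell: np.ndarray
    frac_cleared: np.ndarray  # share of cells with R_M^cell == 0
    frac_fixed: np.ndarray  # share of cells with R_M^cell == 1
    final_r_cell: np.ndarray  # per-cell terminal values (NaN if terminated)
    n_terminated: int = 0
    n_saturated: int = 0  # cells whose copy number hit the divergence guard

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "mean_r_cell": self.mean_r_cell,
                "sd_r_cell": self.sd_r_cell,
                "frac_cleared": self.frac_cleared,
                "frac_fixed": self.frac_fixed,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def clearance_day(self) -> float:
        """First sampled day at which every (non-terminated) cell is mutant-free.

        Returns ``nan`` if the ensemble never fully clears in the horizon.
        """
        cleared = self.frac_cleared >= 1.0
        idx = np.nonzero(cleared)[0]
        return float(self.times[idx[0]]) if idx.size else float("nan")


def run_scenario(spec: ScenarioSpec, master_seed: int = 0) -> EnsembleResult:
    """Run a scenario ensemble; cell k is reproducible from (master_seed, k)."""
    grid = np.arange(0.0, spec.t_end + 1e-9, spec.record_dt)
    r = np.empty((spec.n_cells, grid.shape[0]))
    final = np.empty(spec.n_cells)
    n_term = 0
    n_sat = 0
    for k in range(spec.n_cells):
        cell = premix(spec.params, seed=child_seed(master_seed, k, 0))
        if spec.introduce_mutant:
            rng = np.random.default_rng(child_seed(master_seed, k, 1))
            relabel_random_nucleoid(cell, rng)
        cfg = SimulationConfig(
            t_end=spec.t_end,
            params=spec.params,
            seed=child_seed(master_seed, k, 2),
            record_grid=grid,
            enabled_channels=spec.channels,
        )
        traj = run_cell(cell, cfg)
        r[k] = traj.r_cell
        final[k] = traj.r_cell[-1]
        n_term += int(traj.terminated_empty)
        n_sat += int(traj.saturated)
    mean = np.nanmean(r, axis=0)
    sd = np.nanstd(r, axis=0, ddof=0)
    with np.errstate(invalid="ignore"):
        frac_cleared = np.nanmean(r == 0.0, axis=0)
        frac_fixed = np.nanmean(r == 1.0, axis=0)
    return EnsembleResult(
        spec=spec,
        times=grid,
        mean_r_cell=mean,
        sd_r_cell=sd,
        frac_cleared=frac_cleared,
        frac_fixed=frac_fixed,
        final_r_cell=final,
        n_terminated=n_term,
        n_saturated=n_sat,
    )


def scenario_presets(base: QCParams | None = None) -> dict[str, ScenarioSpec]:
    """Named presets for the standard perturbation panels.

    fig3: nominal selectivity, with/without replicative advantage (RA) and
    with/without fusion selectivity, at τ = 7.5 and 30 days.  fig4: high
    mitophagy selectivity (r_D_max=199, non-selective fusion) and absolute
    fusion selectivity (r_fusion_max=1).  fig6: both selectivities halved
    (aged QC), with τ up to 120 days.
    """
    base = base or QCParams.nominal()
    ra = {"k_R": 2.0}
    nonsel = {"r_fusion_max": 0.0}
    out: dict[str, ScenarioSpec] = {}

    def add(name: str, tau: float, **over) -> None:
        p = scale_for_tau(tau, base).with_(**over)
        out[name] = ScenarioSpec(name=name, params=p)

    for tau in (7.5, 30.0):
        tag = f"tau{tau:g}"
        add(f"fig3A_{tag}_noRA", tau)
        add(f"fig3B_{tag}_RA", tau, **ra)
        add(f"fig3C_{tag}_noRA_nonselectiveFusion", tau, **nonsel)
        add(f"fig3D_{tag}_RA_nonselectiveFusion", tau, **ra, **nonsel)
        add(f"fig4A_highMitophagy_{tag}", tau, r_D_max=199.0, **nonsel)
        add(f"fig4B_highMitophagy_RA_{tag}", tau, r_D_max=199.0, **ra, **nonsel)
        add(f"fig4C_fullFusionSelectivity_{tag}", tau, r_fusion_max=1.0)
        add(f"fig4D_fullFusionSelectivity_RA_{tag}", tau, r_fusion_max=1.0, **ra)
    half = {"r_D_max": base.r_D_max / 2, "r_fusion_max": base.r_fusion_max / 2}
    for tau in (7.5, 30.0, 120.0):
        add(f"fig6A_halfSelectivity_RA_tau{tau:g}", tau, **half, **ra)
        add(f"fig6B_halfSelectivity_noRA_tau{tau:g}", tau, **half)
    # short aliases
    out["fig4A_highMitophagy"] = out["fig4A_highMitophagy_tau7.5"].with_(
        name="fig4A_highMitophagy"
    )
    out["fig6_tau120"] = out["fig6A_halfSelectivity_RA_tau120"].with_(
        name="fig6_tau120"
    )
    return out


@dataclass
class EpisodeStats:
    """Occurrence and lifetime of mutant-rich mitochondria episodes."""

    threshold: float
    occurrence_rate: float  # episode starts per mitochondrion-day
    mean_lifetime: float  # days
    fraction_of_time_rich: float  # share of simulated time with >=1 rich mito
    n_episodes: int
    n_censored: int
    mito_days: float
    n_cells: int

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "occurrence_rate": self.occurrence_rate,
            "mean_lifetime": self.mean_lifetime,
            "fraction_of_time_rich": self.fraction_of_time_rich,
            "n_episodes": self.n_episodes,
            "n_censored": self.n_censored,
            "mito_days": self.mito_days,
            "n_cells": self.n_cells,
        }


def track_mutant_rich_episodes(
    params: QCParams,
    threshold: float = 0.9,
    n_cells: int = 100,
    t_end: float = 300.0,
    seed: int = 0,
) -> EpisodeStats:
    """Episode statistics under fusion-fission alone with non-selective fusion.

    Per cell: premix, relabel one uniformly chosen nucleoid as mutant, run
    fusion-fission only (no turnover) and record maximal intervals during
    which a mitochondrion's mutant fraction exceeds ``threshold``.  The
    occurrence rate normalizes episode starts by mitochondrion-days; the mean
    lifetime averages episode durations (episodes still open at ``t_end``
    are truncated there).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    p = params.with_(r_fusion_max=0.0)
    starts = 0
    dur_sum = 0.0
    n_eps = 0
    n_cens = 0
    mito_days = 0.0
    rich_time = 0.0
    for k in range(n_cells):
        cell = premix(p, seed=child_seed(seed, k, 0))
        rng = np.random.default_rng(child_seed(seed, k, 1))
        relabel_random_nucleoid(cell, rng)
        cfg = SimulationConfig(
            t_end=t_end,
            params=p,
            seed=child_seed(seed, k, 2),
            record_grid=np.array([0.0, t_end]),
            enabled_channels=FUSION_FISSION_ONLY,
            track_episodes=True,
            rich_threshold=threshold,
        )
        log = run_cell(cell, cfg).episodes
        starts += log.n_starts
        dur_sum += log.duration_sum
        n_eps += log.n_starts  # every start has a (possibly truncated) duration
        n_cens += log.n_censored
        mito_days += log.mito_days
        rich_time += log.duration_sum
    occurrence = starts / mito_days if mito_days > 0 else float("nan")
    lifetime = dur_sum / n_eps if n_eps else float("nan")
    return EpisodeStats(
        threshold=threshold,
        occurrence_rate=occurrence,
        mean_lifetime=lifetime,
        fraction_of_time_rich=rich_time / (n_cells * t_end),
        n_episodes=n_eps,
        n_censored=n_cens,
        mito_days=mito_days,
        n_cells=n_cells,
    )
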