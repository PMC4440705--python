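"""Simulate one cell under the full quality-control model.

Builds a premixed cell (fusion-fission burn-in from 32 mitochondria x 10
wild-type nucleoids), relabels one nucleoid as a de novo mutant, and runs
all four reaction channels — replication, mitophagy, fusion, fission — for
120 days, printing weekly snapshots of the cell.
"""

import numpy as np

from mitoqc import QCParams, SimulationConfig, premix, run_cell
from mitoqc.calibration import relabel_random_nucleoid

params = QCParams.nominal()
cell = premix(params, seed=1)
relabel_random_nucleoid(cell, np.random.default_rng(2))
print(f"premixed cell: {cell.n_mitochondria} mitochondria, "
      f"{cell.n_nucleoids} nucleoids, 1 mutant")

cfg = SimulationConfig(
    t_end=120.0, params=params, seed=3,
    record_grid=np.arange(0.0, 121.0, 7.0),
)
traj = run_cell(cell, cfg)

print(f"{'day':>5} {'mitochondria':>13} {'nucleoids':>10} {'R_M^cell':>9}")
for t, nm, nn, r in zip(traj.times, traj.n_mito, traj.n_nucleoids, traj.r_cell):
    print(f"{t:5.0f} {nm:13.0f} {nn:10.0f} {r:9.4f}")

print(
    "\nR_M^cell is the mutant share of all mtDNA nucleoids in the cell; a "
    "single neutral mutant\namong 320 nucleoids usually drifts out within "
    "weeks to months under selective turnover."
)
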