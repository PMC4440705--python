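"""Track mutant-rich mitochondria episodes under fusion-fission alone.

A single mutant nucleoid is occasionally isolated by fission into a
mitochondrion whose mutant fraction exceeds 0.9 (with one mutant: a
mitochondrion of its own).  Faster fusion-fission creates such mutant-rich
mitochondria more often but they survive for less time; the fraction of
time spent mutant-rich is invariant.
"""

from mitoqc import QCParams, scale_for_tau, track_mutant_rich_episodes

nominal = QCParams.nominal()
print(f"{'tau preset':>10} {'occurrence /mito/day':>20} {'lifetime (d)':>13} "
      f"{'product':>10}")
for tau in (7.5, 30.0):
    stats = track_mutant_rich_episodes(
        scale_for_tau(tau, nominal), threshold=0.9, n_cells=40, t_end=300.0,
        seed=6,
    )
    print(f"{tau:10.1f} {stats.occurrence_rate:20.3e} "
          f"{stats.mean_lifetime:13.2f} "
          f"{stats.occurrence_rate * stats.mean_lifetime:10.3e}")

print(
    "\nQuadrupling the mixing time cuts the episode rate ~4x and stretches "
    "each episode ~4x,\nleaving the occurrence x lifetime product — the "
    "time share during which selective\nmitophagy could act — unchanged."
)
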