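"""Replica-exchange DMD plus WHAM heat capacity on a reduced ladder.

Runs a short 9-replica exchange simulation of the bundle, reconstructs
the density of states from the pooled energy histograms and prints the
heat-capacity curve's peak — the folding/unfolding transition
temperature of the toy protein.  A desk-scale miniature of the full
24-replica protocol (see scripts/acceptance.py for that one).
"""

import numpy as np

from dmdrex import build_ladder, build_mini_bundle, mini_bundle_topology, run_rex
from dmdrex.rex import replica_mobility
from dmdrex.units import KB
from dmdrex.wham import EnergyHistogramSet, discard_equilibration, heat_capacity, wham_solve

topology = mini_bundle_topology()
model, state = build_mini_bundle(topology, seed=1)
ladder = build_ladder(0.40, 0.56, 0.02)  # 9 replicas around the transition

ensemble = run_rex(model, state, ladder, n_timesteps=2.0e4,
                   swap_interval=1000.0, seed=5)
counts, mob_mean, mob_sd = replica_mobility(ensemble)
print(f"{len(ladder)} replicas, swap acceptance "
      f"{ensemble.swap_acceptance_rate():.2f}, "
      f"mobility {mob_mean:.1f} +/- {mob_sd:.1f} temperatures/replica")

series = discard_equilibration(ensemble.energy_series, ensemble.energy_times,
                               ladder.temperatures, fraction=1 / 12)
hists = EnergyHistogramSet.from_series(series, bin_width=1.0)
cv = heat_capacity(wham_solve(hists))
peak = cv.peaks[0] if len(cv.peaks) else float("nan")
print(f"heat-capacity peak at T = {peak:.3f} kcal/(mol kB) = {peak / KB:.0f} K")
print("the peak marks the cooperative melting of the helix bundle; the "
      "energy-fluctuation variance is largest where folded and unfolded "
      "states exchange")
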