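"""Simulate vasculogenesis on a desk-scale lattice and summarize the network.

Runs the Cellular-Potts model (64x64, 62 cells, same site density as the full
256x256 / 1000-cell protocol) for 800 Monte-Carlo steps and prints how the
vessel network and its lacunae (enclosed medium regions) look at the end.
"""

import numpy as np

from pottsnet import ModelParams, lacunae_areas, simulate

params = ModelParams(lattice_size=64, n_cells_initial=62)
run = simulate(params, seed=1, mcs_start_save=200, mcs_end=800, save_every=100)

final_mask = run.masks[-1]
areas = lacunae_areas(final_mask).areas
print(f"snapshots saved at MCS {run.mcs_values.tolist()}")
print(f"vessel fraction at MCS 800: {final_mask.mean():.3f} "
      f"({int(final_mask.sum())} of {final_mask.size} sites)")
print(f"lacunae (medium regions >= 3 sites): {len(areas)}, "
      f"median area {np.median(areas):.0f} sites, largest {max(areas)} sites")
print("A healthy parameterization gives a connected vessel mass enclosing many")
print("distinct lacunae -- not one featureless blob, not dispersed cells.")
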