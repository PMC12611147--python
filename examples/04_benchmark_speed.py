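"""Wall-time comparison: 100 MCS of mechanistic simulation vs one U-Net call.

Times both methods on the same freshly settled configurations.  The numbers
are hardware-dependent by nature; what matters is the ratio's order of
magnitude -- one forward pass replaces lattice_size^2 x 100 Monte-Carlo
attempts plus 100 field updates.
"""

from pottsnet import ModelParams, SurrogateConfig, build_surrogate
from pottsnet.cli_orchestration import benchmark

params = ModelParams(lattice_size=64, n_cells_initial=62)
model = build_surrogate(SurrogateConfig(depth=2, base_channels=8, horizon=100, seed=0))

mech, surro = benchmark(model, params, n_replicates=5, seed=0,
                        horizon=100, settle_mcs=100)
for rec in (mech, surro):
    d = rec.to_dict()
    print(f"{d['method']:12s} ({d['device']}): median {d['median_s']:.4f} s, "
          f"sd {d['sd_s']:.4f} s over n={d['n']}")
print(f"speedup (median mechanistic / median surrogate): "
      f"{mech.median_s / surro.median_s:.1f}x")
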