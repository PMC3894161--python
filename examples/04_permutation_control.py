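"""The permutation control: no spatial signal, no lengthscale.

Column-shuffling a simulated alignment preserves every column's data but
destroys the spatial arrangement of rates.  The posterior lengthscale
should collapse toward zero on the shuffled data — the model's own report
that there is no spatial correlation to exploit.
"""

import numpy as np

import phylogp as pg

grid = pg.make_2d_grid(10, 10, spacing=5.0)
field = pg.block_rate_field(grid, block=5)
tree = pg.canonical_tree()
model = pg.build_jtt_model()
rng = np.random.default_rng(9)
aln = pg.simulate_alignment(tree, model, field, rng)
shuffled = pg.shuffle_columns(aln, rng)

cfg = pg.MCMCConfig(n_iterations=3000, seed=2)
intact = pg.infer_rates(aln, tree, grid, cfg)
broken = pg.infer_rates(shuffled, tree, grid, cfg)

print(f"median lengthscale, intact alignment:   {intact.summary.median_lengthscale:6.1f} Å")
print(f"median lengthscale, shuffled alignment: {broken.summary.median_lengthscale:6.1f} Å")
print("(the shuffled fit collapses toward the 5 Å grid spacing — on the "
      "full 400-site problem it falls below it — the model's own signal "
      "that no usable spatial correlation remains)")
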