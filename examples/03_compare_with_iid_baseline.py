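"""Compare the GP-smoothed estimator with the i.i.d. discrete-Gamma model.

Scores both on the same simulated replicate: squared log-rate loss (lower
is better; sensitive to bias) and AUC for ranking the slow, putatively
functional sites first (higher is better; pure discrimination).
"""

import numpy as np

import phylogp as pg

grid = pg.make_2d_grid(10, 10, spacing=5.0)
field = pg.block_rate_field(grid, block=5, low=0.2, high=1.8)
tree = pg.canonical_tree()
model = pg.build_jtt_model()
aln = pg.simulate_alignment(tree, model, field, np.random.default_rng(3))

gp = pg.infer_rates(aln, tree, grid, pg.MCMCConfig(n_iterations=3000, seed=5))
iid = pg.fit_iid_rates(aln, tree, model, n_categories=16)

for name, est in (("GP-smoothed", gp.summary.mean_rate), ("i.i.d. Gamma", iid.rates)):
    rep = pg.evaluate_estimates(field, est, k=10)
    print(f"{name:12s}  loss={rep.loss:.3f}  auc={rep.auc:.3f}  "
          f"top-10 truly slow: {field.functional_mask[rep.top_k_sites].sum()}/10")
# The GP borrows strength from spatial neighbours, so when slow sites are
# clustered its loss is lower and its slow-site ranking cleaner than the
# site-independent Gamma model's.
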