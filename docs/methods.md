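# Methods

## Model

The observable is a protein multiple sequence alignment `X` (N columns)
with a fixed phylogeny `T` (topology and branch lengths are inputs, not
estimated) and one member's tertiary structure.  Each column `i` carries a
latent log substitution rate `r_i`; columns are conditionally independent
given the rates, with likelihood `L_i(exp(r_i))` computed by Felsenstein's
pruning algorithm under the JTT model, branch lengths multiplied by the
site rate.  Gaps and unrecognized residue symbols are missing data (partial
likelihood 1 in every state), so an all-gap column has log-likelihood
exactly 0 at every rate.

The prior on `r` is a zero-mean multivariate normal whose covariance is a
stationary kernel of the pairwise Cα distance matrix.  The assumptions this
encodes, and their limits:

* **Shared rates across the tree.**  The sequences form one family with
  conserved function; rates vary across sites, not over time or lineages.
* **Stationarity/isotropy.**  Correlation depends only on Euclidean Cα
  distance, not direction or position.  Surface vs. core differences enter
  only through the data, not the prior; a structure-feature-dependent mean
  (e.g. linked to solvent accessibility) is out of scope.
* **Zero mean on the log scale.**  The prior centres rates at 1; σ controls
  how far log rates wander from 0.

## Numerical likelihood

Transition matrices come from one eigendecomposition of the symmetrized
generator (`B = Π^{1/2} Q Π^{-1/2}`), so `P(t)` at any branch-length×rate
product is two small matrix products; rows are clipped at 0 and
renormalized to absorb rounding.  Per-site log-likelihoods are cached on an
evenly spaced rate grid (default 4000 points on [0.005, 20]; the lower
bound is `rate_max/grid_size`, keeping the grid "from near zero")
and interpolated **linearly in the rate domain** (`ρ = exp(r)` first);
outside the grid the boundary value is used.  On 4-taxon data the
interpolation error is below 0.01 log-likelihood units across rates in
[0.01, 19] (unit-tested), which is negligible against Monte-Carlo noise.
Partial likelihoods are rescaled per internal node, so deep trees cannot
underflow.

The JTT numerical table (exchangeabilities + equilibrium frequencies,
Jones et al. 1992 as distributed with PAML/phangorn) is stored as TSVs in
`src/phylogp/data/`; the generator is normalized to one expected
substitution per site per unit branch length at equilibrium.  Likelihood
correctness is tested three ways: brute-force enumeration of internal-node
states on 2- and 4-taxon trees, root-placement invariance (pulley
principle), and frozen reference values computed independently with R
phangorn's `pml`.

## Sampler

Two Metropolis blocks per iteration:

1. **Rates** (50 sub-updates/iteration): Neal's underrelaxed proposal
   `r′ = √(1−ε²)·r + ε·L·z`, which leaves the GP prior exactly invariant,
   so the acceptance ratio is the likelihood ratio alone.  Prior invariance
   is verified empirically in the tests rather than assumed.
2. **Hyperparameters**: joint Gaussian random walk on
   `(log ℓ, log σ)`.  The exponential priors are densities on the natural
   scale, so the acceptance ratio carries the explicit Jacobian `ℓ′σ′/ℓσ`.
   Each accepted move rebuilds `K` and its Cholesky factor; a failed
   factorization counts as a rejection.  Repeated builds reuse the
   unique-distance decomposition of `D` (a lattice has O(N) distinct
   distances for N² entries).

Schedule and tuning: the 50:1 rate:hyper update ratio reflects the cost
asymmetry (matrix-vector vs. O(N³) Cholesky).  ε (initial 0.1) and the
hyper step (initial 0.5) adapt every 25 iterations during burn-in by a
Robbins–Monro rule targeting 0.25 acceptance, with gain 1/√round, and are
frozen at burn-in's end so the recorded phase is a valid Markov chain.
Post-burn-in acceptance rates land in [0.1, 0.45] on the study problems.
Defaults: 20 000 iterations, 50% burn-in, thinning 10, two independent
chains pooled for summaries.  Initialization: `r` drawn from the prior at
starting hyperparameters ℓ₀ = 2× mean nearest-neighbour Cα distance,
σ₀ = 1 (keeps the first Cholesky well conditioned).

Per-site point estimates are posterior means of `exp(r)` over pooled
post-burn-in draws (the mean rate, not the exponentiated mean log rate —
the alternative underestimates the rate by the lognormal factor
`exp(var/2)`); intervals are 2.5/97.5% quantiles of `exp(r)`; ℓ and σ are
summarized by medians, which are robust to the heavy right tail the
exponential prior permits.

## Priors and defaults

| parameter | default | why |
|---|---|---|
| kernel | Matérn 1.5 | least smooth of the three; tolerates small patches and sharp rate changes between neighbours |
| jitter δ | 1e−6 | stabilizes the Cholesky without visibly changing the kernel |
| prior mean of ℓ | 100 Å | weakly informative over protein-sized domains (tens of Å) |
| prior mean of σ | 10 | admits log-rate spreads far beyond the ~±1.6 of a 0.2/1.8 field |
| Gamma categories (baseline) | 16 | finer than the common 4, to make the i.i.d. comparator as strong as practical |

The exponential hyperpriors are parameterized by their **means**.  The
alternative (rate parameterization with a large rate) concentrates mass
near zero and is strongly informative, which contradicts the intent of a
weak prior; sensitivity: with 400 sites the ℓ likelihood is sharp enough
that halving or doubling the prior means moves the posterior medians by
far less than the between-replicate spread (the permutation control, where
the likelihood carries no spatial signal, is the regime where the prior
matters most — there the posterior ℓ collapses toward 0 regardless,
because small ℓ maximizes the prior density of a spatially incoherent
`r`).

## Synthetic data

The generator reproduces the canonical study conditions: a 4-taxon quartet
with every branch 0.2 (total tree length 1 — about one substitution per
site, deliberately information-poor), JTT, and a 20×20 lattice at 5 Å
spacing (the typical Cα distance of physically contacting residues)
carrying a checkerboard of rates 0.2/1.8, block size 10 (configuration 1)
or 5 (configuration 2); both average rate 1 exactly, and the slow half of
the sites is flagged functional for ROC purposes.  Alignments are sampled
by drawing the root from equilibrium and transitioning along branches with
`P(branch × rate)`; an independent Gillespie jump-chain simulator provides
substitution *counts* and serves as a second route for validating the
endpoint distribution.  No indels are simulated, and rates are constant
within a site across the tree — matching the model's own assumptions, so
simulation tests validate inference, not model robustness.  What passing
them does **not** show: performance under misspecified structure (wrong
coordinates), indel-rich alignments, lineage-specific rate shifts, or real
equilibrium-frequency deviations from JTT.

The column-shuffling control permutes alignment columns uniformly,
preserving each column's data while destroying the spatial arrangement;
the posterior lengthscale collapsing below one grid spacing on shuffled
data is the model's report of "no spatial correlation".

## Study-scale choices

The packaged study (tests and `scripts/acceptance.py`) uses 5 replicates
per configuration, 2 chains × 5000 iterations per replicate — sizes chosen
so the whole study re-runs in minutes while keeping the between-replicate
spread of posterior-median ℓ small compared to the configuration-1 vs
configuration-2 separation.  Under these sizes the recovered median ℓ is
roughly threefold larger for 10×10 blocks than 5×5 blocks, the GP's median
log-rate loss is well below the i.i.d. baseline's, and its mean AUC at
least as high; production analyses should use the 20 000-iteration
default and inspect the split-R̂ diagnostic on ℓ.

## The i.i.d. baseline

`fit_iid_rates` is a re-implementation of the discrete-Gamma
empirical-Bayes estimator class that Rate4Site represents: equal-probability
quantile categories of a mean-1 Gamma (each category its conditional mean,
so the discretized mean is exactly 1), shape fitted by bounded 1-D maximum
likelihood, per-site estimates as posterior-mean rates over categories.  It
is a comparator of the same model class, **not** a port of Rate4Site;
comparisons in this package are against this baseline.  Degenerate corner:
an alignment of invariant columns has a likelihood monotone in the shape
parameter and the fit lands at the *lower* optimization bound (small shapes
put most equal-probability categories near rate 0, which invariant columns
favor under the fixed mean-1 constraint); per-site rates are then equal
across sites, as they should be.

## Evaluation

Loss is the mean squared difference of **log** rates — the log scale
emphasizes differences among the low, conservation-relevant rates and
penalizes systematic bias that ROC analysis cannot see.  (Absolute rather
than squared log differences would be a one-line change in
`log_rate_loss`.)  ROC ranks sites by estimated rate ascending with slow
sites as positives; ties count half, so the AUC equals the normalized
Mann–Whitney statistic; replicate curves are averaged vertically on a
common FPR grid.  Top-k extraction breaks rate ties toward the smaller
site index, deterministically.

## Degenerate inputs and tie-breaks

* N = 1 structures run as a pure i.i.d. special case (K is 1×1).
* Duplicate coordinates (d = 0 off-diagonal) stay positive-definite thanks
  to the jitter.
* Zero-length branches are legal (P(0) = I); negative lengths are format
  errors.
* Columns where the structure's reference sequence is gapped are excluded
  from the model (coordinates cannot be imputed), with a warning.
* A Cholesky failure during hyper proposals rejects the proposal rather
  than aborting the chain.

## Known limitations

* JTT only (the model type is pluggable but no other matrix ships).
* No tree or branch-length estimation; errors in the input tree propagate
  into rates unexamined.
* Dense Cholesky per hyper update: O(N³) limits practical alignments to a
  few thousand structured sites; no sparse-GP approximation.
* No marginal-likelihood/Bayes-factor machinery for formal model
  comparison against the i.i.d. model.
* mmCIF input and solvent-accessibility covariates are not supported.
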