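"""Ground-truth rate fields and simulated alignments for the 2D toy-protein
study.

The canonical study design: four sequences related by an unrooted quartet
with every branch length 0.2 (total tree length 1.0, so an average site
carries about one substitution), JTT substitutions, and a 20x20 lattice
structure with 5 Å spacing carrying a checkerboard of slow (0.2) and fast
(1.8) rate blocks.  Two block sizes are studied: 10x10 (configuration 1,
strong spatial correlation) and 5x5 (configuration 2, weaker correlation).
In both, exactly half the sites are slow, so the mean rate is 1.  A
column-shuffled variant of configuration 1 destroys the spatial pattern
while preserving the per-column data, serving as a no-correlation control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phylo_core import Alignment, PhyloTree, SubstitutionModel, read_newick
from .structures import StructureCoords

__all__ = [
    "CANONICAL_TREE_NEWICK",
    "canonical_tree",
    "RateField",
    "block_rate_field",
    "simulate_alignment",
    "simulate_site_histories",
    "shuffle_columns",
]

#: The 4-taxon simulation tree: every branch 0.2, total length 1.0.
CANONICAL_TREE_NEWICK = "((A:0.2,B:0.2):0.2,C:0.2,D:0.2);"


def canonical_tree() -> PhyloTree:
    """The canonical 4-taxon quartet with all branch lengths 0.2."""
    return read_newick(CANONICAL_TREE_NEWICK)


@dataclass
class RateField:
    """True per-site substitution rates bound to a structure.

    ``functional_mask`` flags the slow (putatively functional) sites.
    """

    rates: np.ndarray  # (N,) > 0
    functional_mask: np.ndarray  # (N,) bool
    coords: StructureCoords | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.functional_mask = np.asarray(self.functional_mask, dtype=bool)
        if np.any(~np.isfinite(self.rates)) or np.any(self.rates <= 0):
            raise ValueError("rates must be positive and finite")
        if self.functional_mask.shape != self.rates.shape:
            raise ValueError("mask length must match rates")

    @property
    def n_sites(self) -> int:
        return len(self.rates)


def block_rate_field(
    grid: StructureCoords, block: int, low: float = 0.2, high: float = 1.8
) -> RateField:
    """Checkerboard rate field on a 2D grid: alternating square blocks of
    slow (``low``) and fast (``high``) sites; the slow sites are flagged
    functional.  Grid dimensions must be divisible by ``block``."""
    if grid.grid_shape is None:
        raise ValueError("block_rate_field requires a grid from make_2d_grid")
    rows, cols = grid.grid_shape
    if rows % block or cols % block:
        raise ValueError(f"grid {rows}x{cols} not divisible by block {block}")
    rr, cc = np.divmod(np.arange(rows * cols), cols)
    slow = ((rr // block) + (cc // block)) % 2 == 0
    rates = np.where(slow, low, high)
    return RateField(rates, slow, coords=grid)


def _sample_rows(p_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one categorical sample per row of a stochastic matrix."""
    cum = np.cumsum(p_rows, axis=1)
    u = rng.random(p_rows.shape[0])
    return np.minimum((u[:, None] > cum).sum(axis=1), p_rows.shape[1] - 1)


def simulate_alignment(
    tree: PhyloTree,
    model: SubstitutionModel,
    field: RateField,
    rng: np.random.Generator,
) -> Alignment:
    """Evolve each site independently down the tree at its own rate.

    Root states are drawn from the model equilibrium; each branch applies
    the transition matrix at (branch length x site rate).  Columns appear in
    field (structure) order; no indels are simulated.
    """
    n_sites = field.n_sites
    n_nodes = max(tree.children) + 1
    states = np.empty((n_nodes, n_sites), dtype=np.int64)
    # preorder: root first, then edges top-down (reverse of postorder works
    # because every parent appears after its children in postorder)
    for rate in np.unique(field.rates):
        cols = np.flatnonzero(field.rates == rate)
        states[tree.root, cols] = _sample_rows(
            np.tile(model.equilibrium_freqs, (len(cols), 1)), rng
        )
        for parent in reversed(tree.postorder):
            for child, bl in tree.children[parent]:
                p = model.transition_matrix(bl * rate)
                states[child, cols] = _sample_rows(p[states[parent, cols]], rng)
    codes = states[: tree.n_leaves].astype(np.int8)
    return Alignment(list(tree.taxon_names), codes)


def simulate_site_histories(
    tree: PhyloTree,
    model: SubstitutionModel,
    rate: float,
    n_sites: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact jump-chain (Gillespie) simulation at a single rate.

    Returns ``(leaf_states, n_substitutions)`` where ``n_substitutions``
    counts every substitution event on every branch — not just the visible
    endpoint differences — so the expected count per site equals
    ``rate * total_branch_length`` under the mean-1 generator.
    """
    Q = model.rate_matrix
    exit_rates = -np.diag(Q)
    jump = Q / exit_rates[:, None]
    np.fill_diagonal(jump, 0.0)
    cum_jump = np.cumsum(jump, axis=1)

    n_nodes = max(tree.children) + 1
    states = np.empty((n_nodes, n_sites), dtype=np.int64)
    n_subs = np.zeros(n_sites, dtype=np.int64)
    states[tree.root] = _sample_rows(np.tile(model.equilibrium_freqs, (n_sites, 1)), rng)
    for parent in reversed(tree.postorder):
        for child, bl in tree.children[parent]:
            t_total = bl * rate
            s = states[parent].copy()
            t = rng.exponential(1.0 / exit_rates[s])
            alive = t < t_total
            while np.any(alive):
                idx = np.flatnonzero(alive)
                u = rng.random(len(idx))
                s[idx] = np.minimum(
                    (u[:, None] > cum_jump[s[idx]]).sum(axis=1), 19
                )
                n_subs[idx] += 1
                t[idx] += rng.exponential(1.0 / exit_rates[s[idx]])
                alive = t < t_total
            states[child] = s
    return states[: tree.n_leaves], n_subs


def shuffle_columns(
    alignment: Alignment,
    rng: np.random.Generator,
    return_permutation: bool = False,
):
    """Uniformly random permutation of alignment columns.

    Destroys any spatial arrangement of per-column signal while preserving
    the multiset of columns.  With ``return_permutation`` the applied
    permutation is returned too (``new_column_j = old_column_perm[j]``).
    """
    perm = rng.permutation(alignment.n_sites)
    shuffled = Alignment(list(alignment.taxon_names), alignment.codes[:, perm])
    return (shuffled, perm) if return_permutation else shuffled
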