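"""Phylogenetic machinery: alignments, trees, the JTT model and the
per-site pruning likelihood with its rate-grid cache.

The likelihood of one alignment column is computed by Felsenstein's pruning
algorithm under a reversible amino-acid substitution model (JTT), with the
branch lengths scaled by a site-specific substitution rate.  Because MCMC
over per-site rates evaluates the likelihood millions of times, the
site-specific log-likelihoods are pre-computed once on a fine, evenly spaced
grid of rates and later obtained by linear interpolation in the rate (not
log-rate) domain; rates outside the grid are clamped to the nearest
boundary.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "GAP_CODE",
    "FormatError",
    "Alignment",
    "PhyloTree",
    "SubstitutionModel",
    "SiteLikelihoodCache",
    "read_alignment",
    "read_newick",
    "build_jtt_model",
    "site_log_likelihood",
    "loglik_matrix",
    "build_cache",
    "interp_log_likelihood",
]

#: Canonical amino-acid order (the PAML convention, matching the bundled JTT
#: data files).
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Integer code for gap / unknown residues (treated as missing data).
GAP_CODE = 20

_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_CODE["-"] = GAP_CODE
_CODE["."] = GAP_CODE
_CODE["X"] = GAP_CODE


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as the expected format."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """A protein multiple sequence alignment.

    Residues are stored as integer codes 0..19 in :data:`AMINO_ACIDS` order;
    gaps, ``X`` and any non-canonical symbol share :data:`GAP_CODE` and are
    treated as missing data by the likelihood.
    """

    taxon_names: list[str]
    codes: np.ndarray  # (n_taxa, n_sites) int8

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxon_names):
            raise ValueError("codes must be (n_taxa, n_sites)")
        if self.codes.shape[1] < 1:
            raise FormatError("alignment has no columns")

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def column(self, i: int) -> dict[str, str]:
        """Residues of column ``i`` as a taxon -> one-letter-symbol mapping."""
        sym = AMINO_ACIDS + "-"
        return {t: sym[c] for t, c in zip(self.taxon_names, self.codes[:, i])}

    def sequence(self, taxon: str) -> str:
        sym = AMINO_ACIDS + "-"
        row = self.codes[self.taxon_names.index(taxon)]
        return "".join(sym[c] for c in row)

    @classmethod
    def from_sequences(cls, taxon_names: Sequence[str], sequences: Sequence[str]) -> "Alignment":
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise FormatError(f"ragged alignment: sequence lengths {sorted(lengths)}")
        codes = np.array(
            [[_CODE.get(c, GAP_CODE) for c in seq.upper()] for seq in sequences],
            dtype=np.int8,
        )
        return cls(list(taxon_names), codes)

    def take_columns(self, columns: Sequence[int]) -> "Alignment":
        """Sub-alignment restricted to the given columns (in the given order)."""
        return Alignment(list(self.taxon_names), self.codes[:, np.asarray(columns, dtype=int)])

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in self.taxon_names:
                fh.write(f">{name}\n{self.sequence(name)}\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read a protein alignment in FASTA or (relaxed) PHYLIP format.

    The format is sniffed from the first non-blank character (``>`` means
    FASTA).  Sequences are upper-cased; any symbol that is not one of the 20
    canonical amino acids or a gap is mapped to missing data (``X``).
    """
    from Bio import AlignIO

    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise FormatError(f"cannot read alignment file {path}: {exc}") from exc
    stripped = text.lstrip()
    if not stripped:
        raise FormatError(f"empty alignment file: {path}")
    fmt = "fasta" if stripped.startswith(">") else "phylip-relaxed"
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise FormatError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(msa) < 2:
        raise FormatError(f"alignment {path} has fewer than 2 sequences")
    return Alignment.from_sequences([rec.id for rec in msa], [str(rec.seq) for rec in msa])


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


@dataclass
class PhyloTree:
    """A phylogeny with fixed topology and branch lengths.

    Nodes are integers; leaves are ``0..n_leaves-1`` in ``taxon_names``
    order.  ``children[v]`` lists ``(child, branch_length)`` pairs for every
    internal node ``v``; ``postorder`` lists the internal nodes in post-order
    with the root last.  Trees read from unrooted Newick strings are rooted
    at an arbitrary internal node; under a reversible model the likelihood
    does not depend on that choice (pulley principle).
    """

    taxon_names: list[str]
    children: dict[int, list[tuple[int, float]]]
    postorder: list[int]

    @property
    def n_leaves(self) -> int:
        return len(self.taxon_names)

    @property
    def root(self) -> int:
        return self.postorder[-1]

    @property
    def total_branch_length(self) -> float:
        return float(sum(bl for kids in self.children.values() for _, bl in kids))

    def edges(self) -> Iterable[tuple[int, int, float]]:
        """Yield (parent, child, branch_length) for every edge."""
        for parent, kids in self.children.items():
            for child, bl in kids:
                yield parent, child, bl


def read_newick(path_or_string: str | Path, default_branch_length: float | None = None) -> PhyloTree:
    """Read a Newick tree (from a file path or a literal Newick string).

    Every edge must carry a branch length unless ``default_branch_length``
    is given.  Negative branch lengths are rejected; zero is allowed.
    """
    import dendropy

    s = str(path_or_string)
    try:
        if "(" in s and ";" in s:
            tree = dendropy.Tree.get(data=s, schema="newick")
        else:
            tree = dendropy.Tree.get(path=s, schema="newick")
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"cannot parse Newick input: {exc}") from exc

    leaves = [lf for lf in tree.leaf_node_iter()]
    taxon_names = [lf.taxon.label if lf.taxon else "" for lf in leaves]
    if len(set(taxon_names)) != len(taxon_names) or "" in taxon_names:
        raise FormatError("tree leaves must carry unique labels")

    index = {id(lf): i for i, lf in enumerate(leaves)}
    children: dict[int, list[tuple[int, float]]] = {}
    postorder: list[int] = []
    next_id = len(leaves)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        index[id(node)] = next_id
        next_id += 1
        kids = []
        for ch in node.child_nodes():
            bl = ch.edge.length
            if bl is None:
                if default_branch_length is None:
                    raise FormatError("missing branch length and no default configured")
                bl = default_branch_length
            if not np.isfinite(bl) or bl < 0:
                raise FormatError(f"invalid branch length {bl!r}")
            kids.append((index[id(ch)], float(bl)))
        children[index[id(node)]] = kids
        postorder.append(index[id(node)])

    root_id = index[id(tree.seed_node)]
    # collapse a degree-2 root introduced by a rooted reading of an unrooted
    # string only if it has a single child (degenerate newick); otherwise keep
    if not postorder:
        raise FormatError("tree has no internal node")
    assert postorder[-1] == root_id
    return PhyloTree(taxon_names, children, postorder)


# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------


@dataclass
class SubstitutionModel:
    """A reversible amino-acid substitution model.

    ``rate_matrix`` is the generator Q with rows summing to zero, scaled so
    that one unit of branch length corresponds to one expected substitution
    per site at equilibrium.  Transition matrices P(t) = expm(Qt) are
    obtained from the eigendecomposition of the symmetrized generator, so
    evaluating P at many branch-length/rate products is cheap.
    """

    name: str
    exchangeabilities: np.ndarray  # (20, 20) symmetric, zero diagonal
    equilibrium_freqs: np.ndarray  # (20,) sums to 1
    rate_matrix: np.ndarray  # (20, 20)
    _eigvals: np.ndarray = field(repr=False, default=None)
    _left: np.ndarray = field(repr=False, default=None)   # D^{-1/2} U
    _right: np.ndarray = field(repr=False, default=None)  # U^T D^{1/2}

    def __post_init__(self) -> None:
        if self._eigvals is None:
            pi = self.equilibrium_freqs
            d = np.sqrt(pi)
            sym = (self.rate_matrix * d[:, None]) / d[None, :]
            sym = 0.5 * (sym + sym.T)  # enforce exact symmetry
            w, u = np.linalg.eigh(sym)
            self._eigvals = w
            self._left = u / d[:, None]
            self._right = u.T * d[None, :]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) for one branch-length/rate product ``t`` (>= 0)."""
        if t < 0:
            raise ValueError("branch length * rate must be non-negative")
        p = (self._left * np.exp(self._eigvals * t)) @ self._right
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Batched P(t) for an array of products, shape (len(ts), 20, 20)."""
        ts = np.asarray(ts, dtype=float)
        e = np.exp(np.multiply.outer(ts, self._eigvals))  # (T, 20)
        p = np.einsum("ab,tb,bc->tac", self._left, e, self._right, optimize=True)
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p


def _load_table(name: str) -> np.ndarray:
    ref = importlib.resources.files("phylogp.data").joinpath(name)
    rows = []
    header_skipped = False
    for line in ref.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        if not header_skipped:
            header_skipped = True  # column header line
            continue
        rows.append(line.split("\t")[1:])  # drop row label
    return np.array(rows, dtype=float)


def build_jtt_model() -> SubstitutionModel:
    """The JTT amino-acid model with the generator normalized to mean rate 1."""
    S = _load_table("jtt_exchangeabilities.tsv")
    pi = _load_table("jtt_frequencies.tsv").ravel()
    pi = pi / pi.sum()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -float(pi @ np.diag(Q))
    Q /= mean_rate
    return SubstitutionModel("JTT", S, pi, Q)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------


def _leaf_partials(codes: np.ndarray) -> np.ndarray:
    """Per-leaf conditional likelihoods, shape (n_taxa, n_sites, 20).

    A resolved residue gives an indicator row; gaps/unknowns give all ones
    (missing data), so a gap contributes a factor of one to the likelihood.
    """
    n_taxa, n_sites = codes.shape
    eye = np.vstack([np.eye(20), np.ones(20)])  # row GAP_CODE -> ones
    return eye[codes]  # fancy-index -> (n_taxa, n_sites, 20)


def _prune_columns(
    leaf_partials: np.ndarray,
    tree: PhyloTree,
    pmats: dict[int, np.ndarray],
    pi: np.ndarray,
) -> np.ndarray:
    """Log-likelihood of every column given per-edge transition matrices.

    ``pmats`` maps child-node id -> P(branch_length * rate).  Partial
    likelihoods are rescaled per internal node to avoid underflow on deep
    trees; the rescaling cancels exactly in the returned log values.
    """
    n_sites = leaf_partials.shape[1]
    partials: dict[int, np.ndarray] = {i: leaf_partials[i] for i in range(tree.n_leaves)}
    log_scale = np.zeros(n_sites)
    for node in tree.postorder:
        m = np.ones((n_sites, 20))
        for child, _bl in tree.children[node]:
            m *= partials.pop(child) @ pmats[child].T
        peak = m.max(axis=1)
        nz = peak > 0
        log_scale[nz] += np.log(peak[nz])
        log_scale[~nz] = -np.inf
        m[nz] /= peak[nz, None]
        partials[node] = m
    root = partials[tree.root]
    lik = root @ pi
    out = np.full(n_sites, -np.inf)
    ok = lik > 0
    out[ok] = np.log(lik[ok]) + log_scale[ok]
    return out


def loglik_matrix(
    alignment: Alignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    rates: np.ndarray,
) -> np.ndarray:
    """Per-site pruning log-likelihoods at each rate; shape (n_sites, len(rates)).

    Branch lengths are multiplied by the rate before computing transition
    matrices.  Columns consisting solely of gaps contribute log-likelihood 0
    at every rate.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("substitution rates must be > 0")
    order = {t: i for i, t in enumerate(alignment.taxon_names)}
    missing = [t for t in tree.taxon_names if t not in order]
    if missing:
        raise ValueError(f"tree taxa absent from alignment: {missing}")
    codes = alignment.codes[[order[t] for t in tree.taxon_names]]
    leafp = _leaf_partials(codes)

    edge_children = [child for _p, child, _bl in tree.edges()]
    edge_lengths = np.array([bl for _p, _c, bl in tree.edges()])
    # all (edge, rate) products in one batched eigen-exponential
    prods = np.multiply.outer(rates, edge_lengths).ravel()
    pall = model.transition_matrices(prods).reshape(len(rates), len(edge_lengths), 20, 20)

    out = np.empty((alignment.n_sites, len(rates)))
    pi = model.equilibrium_freqs
    for g in range(len(rates)):
        pmats = {child: pall[g, e] for e, child in enumerate(edge_children)}
        out[:, g] = _prune_columns(leafp, tree, pmats, pi)
    return out


def site_log_likelihood(
    column: Mapping[str, str],
    tree: PhyloTree,
    model: SubstitutionModel,
    rate: float,
) -> float:
    """Pruning log-likelihood of a single column (taxon -> residue mapping)."""
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    missing = [t for t in tree.taxon_names if t not in column]
    if missing:
        raise ValueError(f"column lacks residues for taxa: {missing}")
    aln = Alignment.from_sequences(tree.taxon_names, [column[t] for t in tree.taxon_names])
    return float(loglik_matrix(aln, tree, model, np.array([rate]))[0, 0])


# ---------------------------------------------------------------------------
# Rate-grid cache with linear interpolation
# ---------------------------------------------------------------------------


@dataclass
class SiteLikelihoodCache:
    """Per-site log-likelihoods tabulated on an evenly spaced rate grid."""

    rate_grid: np.ndarray  # (G,) strictly increasing, uniform spacing
    table: np.ndarray  # (n_sites, G)

    def __post_init__(self) -> None:
        steps = np.diff(self.rate_grid)
        if len(self.rate_grid) < 2 or np.any(steps <= 0):
            raise ValueError("rate grid must be increasing with >= 2 points")
        if not np.allclose(steps, steps[0], rtol=1e-8):
            raise ValueError("rate grid must be evenly spaced")

    @property
    def n_sites(self) -> int:
        return self.table.shape[0]

    @property
    def rate_min(self) -> float:
        return float(self.rate_grid[0])

    @property
    def rate_max(self) -> float:
        return float(self.rate_grid[-1])

    @property
    def spacing(self) -> float:
        return float(self.rate_grid[1] - self.rate_grid[0])

    def interp_all(self, log_rates: np.ndarray) -> np.ndarray:
        """Interpolated log-likelihood of every site at its own log rate.

        The interpolation is linear in the rate domain, so ``exp`` is applied
        first; rates beyond the grid are clamped to the boundary value.
        """
        rho = np.exp(np.asarray(log_rates, dtype=float))
        rho = np.clip(rho, self.rate_min, self.rate_max)
        pos = (rho - self.rate_min) / self.spacing
        idx = np.minimum(pos.astype(int), len(self.rate_grid) - 2)
        frac = pos - idx
        rows = np.arange(self.n_sites)
        return (1.0 - frac) * self.table[rows, idx] + frac * self.table[rows, idx + 1]


def build_cache(
    alignment: Alignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    grid_size: int = 4000,
    rate_max: float = 20.0,
    rate_min: float | None = None,
) -> SiteLikelihoodCache:
    """Tabulate per-site log-likelihoods on ``grid_size`` evenly spaced rates.

    ``rate_min`` defaults to ``rate_max / grid_size`` (0.005 under the
    defaults), giving a near-zero lower bound consistent with even spacing.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if rate_min is None:
        rate_min = rate_max / grid_size
    if not (0 < rate_min < rate_max):
        raise ValueError(f"need 0 < rate_min < rate_max, got {rate_min}, {rate_max}")
    grid = np.linspace(rate_min, rate_max, grid_size)
    return SiteLikelihoodCache(grid, loglik_matrix(alignment, tree, model, grid))


def interp_log_likelihood(cache: SiteLikelihoodCache, site: int, log_rate: float) -> float:
    """Interpolated log-likelihood of one site at one log substitution rate."""
    rho = float(np.exp(log_rate))
    rho = min(max(rho, cache.rate_min), cache.rate_max)
    pos = (rho - cache.rate_min) / cache.spacing
    idx = min(int(pos), len(cache.rate_grid) - 2)
    frac = pos - idx
    return float((1.0 - frac) * cache.table[site, idx] + frac * cache.table[site, idx + 1])
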