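"""Residue coordinates and C-alpha distance matrices.

Coordinates come either from a real PDB structure (one C-alpha per residue)
or from a synthetic 2D lattice "toy protein" whose adjacent residues sit a
fixed spacing apart — a convenient geometry for simulation studies because
rate fields on it can be visualized as heatmaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .phylo_core import Alignment, GAP_CODE

__all__ = [
    "StructureCoords",
    "make_2d_grid",
    "read_pdb_ca",
    "map_structure_to_alignment",
    "pairwise_distances",
]


@dataclass
class StructureCoords:
    """Per-site coordinates (Å) in 2D or 3D.

    ``site_ids`` identify sites in user-facing terms: residue sequence
    numbers for PDB input, 0-based alignment column indices after mapping,
    row-major lattice indices for synthetic grids.  ``grid_shape`` is set
    only by :func:`make_2d_grid`.
    """

    site_ids: np.ndarray  # (N,) int
    coords: np.ndarray  # (N, 2) or (N, 3) float, Å
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[0] != len(self.site_ids):
            raise ValueError("coords must be (N, dim) matching site_ids")

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]


def make_2d_grid(rows: int, cols: int, spacing: float = 5.0) -> StructureCoords:
    """A rows x cols planar lattice with adjacent points ``spacing`` Å apart.

    Sites are ordered row-major (site ``i`` is at row ``i // cols``, column
    ``i % cols``), mirroring the column order of a simulated alignment.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([cc.ravel() * spacing, rr.ravel() * spacing]).astype(float)
    return StructureCoords(np.arange(rows * cols), coords, grid_shape=(rows, cols))


def read_pdb_ca(path: str | Path, chain: str) -> StructureCoords:
    """C-alpha coordinates of one chain, ordered by residue sequence number.

    Uses the first model of multi-model files; heteroatoms and insertion
    codes are ignored; for alternate locations the first conformer is taken.
    Standard residues lacking a C-alpha are skipped with a warning.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    chains = {c.id: c for c in model.get_chains()}
    if chain not in chains:
        raise ValueError(f"chain {chain!r} not in PDB file; available: {sorted(chains)}")
    ids, xyz, skipped = [], [], []
    for res in chains[chain].get_residues():
        hetflag, resseq, icode = res.id
        if hetflag.strip():
            continue  # heteroatom / water
        if "CA" not in res:
            skipped.append(resseq)
            continue
        atom = res["CA"]
        if atom.is_disordered():
            atom = atom.disordered_get_list()[0]
        ids.append(resseq)
        xyz.append(atom.coord)
    if skipped:
        warnings.warn(f"skipped {len(skipped)} residues lacking CA: {skipped}")
    return StructureCoords(np.array(ids), np.array(xyz, dtype=float))


def map_structure_to_alignment(
    coords: StructureCoords, alignment: Alignment, ref_taxon: str
) -> StructureCoords:
    """Assign structure residues to the alignment columns of ``ref_taxon``.

    Structure residue ``k`` maps to the k-th column in which the reference
    sequence is ungapped; the ungapped reference length must equal the
    number of structure residues.  Columns where the reference is gapped
    have no coordinates and are excluded from the model (a warning reports
    how many).  The returned ``site_ids`` are 0-based alignment columns.
    """
    if ref_taxon not in alignment.taxon_names:
        raise ValueError(f"reference taxon {ref_taxon!r} not in alignment")
    row = alignment.codes[alignment.taxon_names.index(ref_taxon)]
    ungapped_cols = np.flatnonzero(row != GAP_CODE)
    if len(ungapped_cols) != coords.n_sites:
        raise ValueError(
            f"length mismatch: reference {ref_taxon!r} has {len(ungapped_cols)} "
            f"ungapped columns but the structure has {coords.n_sites} residues"
        )
    excluded = alignment.n_sites - len(ungapped_cols)
    if excluded:
        warnings.warn(
            f"{excluded} alignment columns are gapped in {ref_taxon!r} "
            "and are excluded from the spatial model"
        )
    return StructureCoords(ungapped_cols, coords.coords.copy())


def pairwise_distances(coords: StructureCoords) -> np.ndarray:
    """Symmetric Euclidean distance matrix (Å) with zero diagonal."""
    if coords.n_sites == 1:
        return np.zeros((1, 1))
    return squareform(pdist(coords.coords))
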