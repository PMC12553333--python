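"""Peptide sequence -> molecular graph for the structure-based models.

A sequence over the 20 canonical amino acids is condensed residue-by-residue
into the linear peptide (one water removed per peptide bond) and returned as
a heavy-atom graph: nodes are atoms, edges are covalent bonds.  Hydrogens are
implicit and no 3D coordinates are used anywhere.  Atom features are a one-hot
element encoding over a configurable palette plus a scaled degree; bond
features are a one-hot over {single, double, aromatic}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from rdkit import Chem

from .core import CANONICAL_AA
from .errors import UnknownElement, UnsupportedResidue

#: Heavy-atom elements occurring in the 20 canonical amino acids.
DEFAULT_PALETTE: Tuple[str, ...] = ("C", "N", "O", "S")

BOND_ORDERS = ("single", "double", "aromatic")
#: Degree scaling constant: heavy-atom degree in peptides is at most 4.
MAX_DEGREE = 4


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph of a linear peptide.

    ``edges`` stores each undirected bond once as ``(u, v)`` with ``u < v``;
    ``bond_orders`` holds the matching entry of :data:`BOND_ORDERS`.
    Feature arrays are attached by :func:`featurize_atoms` /
    :func:`featurize_bonds`.
    """

    atom_elements: List[str]
    edges: List[Tuple[int, int]]
    bond_orders: List[str]
    node_features: np.ndarray = field(default=None)  # (n_atoms, d_node)
    edge_features: np.ndarray = field(default=None)  # (n_edges, d_edge)
    smiles: str = ""

    @property
    def n_atoms(self) -> int:
        return len(self.atom_elements)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_atoms, dtype=np.int64)
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def directed_edges(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Both directed copies of each bond: (src, dst, undirected index)."""
        if self.n_edges == 0:
            z = np.zeros(0, dtype=np.int64)
            return z, z.copy(), z.copy()
        e = np.asarray(self.edges, dtype=np.int64)
        src = np.concatenate([e[:, 0], e[:, 1]])
        dst = np.concatenate([e[:, 1], e[:, 0]])
        idx = np.concatenate([np.arange(self.n_edges)] * 2)
        return src, dst, idx


def sequence_to_peptide_graph(sequence: str, featurize: bool = True) -> MolecularGraph:
    """Build the heavy-atom graph of the linear peptide for ``sequence``.

    Only the 20 canonical one-letter codes are accepted; anything else
    raises :class:`UnsupportedResidue`.  The resulting graph is connected
    and self-loop free.  ``featurize=True`` attaches the default atom and
    bond feature arrays.
    """
    if not sequence:
        raise UnsupportedResidue("empty sequence has no peptide graph")
    sequence = sequence.upper()
    bad = sorted({ch for ch in sequence if ch not in CANONICAL_AA})
    if bad:
        raise UnsupportedResidue(
            f"non-canonical residue(s) {bad} cannot be condensed into a peptide"
        )
    mol = Chem.MolFromSequence(sequence)
    if mol is None:  # pragma: no cover - guarded by the alphabet check
        raise UnsupportedResidue(f"could not build peptide for {sequence!r}")
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    edges: List[Tuple[int, int]] = []
    orders: List[str] = []
    for b in mol.GetBonds():
        u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if b.GetIsAromatic() or b.GetBondType() == Chem.BondType.AROMATIC:
            order = "aromatic"
        elif b.GetBondType() == Chem.BondType.DOUBLE:
            order = "double"
        else:
            order = "single"
        edges.append((min(u, v), max(u, v)))
        orders.append(order)
    g = MolecularGraph(atom_elements=elements, edges=edges, bond_orders=orders,
                       smiles=Chem.MolToSmiles(mol))
    if featurize:
        g.node_features = featurize_atoms(g)
        g.edge_features = featurize_bonds(g)
    return g


def featurize_atoms(
    graph: MolecularGraph,
    element_palette: Sequence[str] = DEFAULT_PALETTE,
) -> np.ndarray:
    """One-hot element over the palette, concatenated with degree / 4.

    Feature width is ``len(palette) + 1``; every row sums to
    ``1 + degree/4``.
    """
    lut = {el: i for i, el in enumerate(element_palette)}
    deg = graph.degrees()
    out = np.zeros((graph.n_atoms, len(element_palette) + 1), dtype=np.float64)
    for i, el in enumerate(graph.atom_elements):
        if el not in lut:
            raise UnknownElement(f"element {el!r} not in palette {tuple(element_palette)}")
        out[i, lut[el]] = 1.0
        out[i, -1] = deg[i] / MAX_DEGREE
    return out


def featurize_bonds(graph: MolecularGraph) -> np.ndarray:
    """One-hot bond order over {single, double, aromatic}, one row per
    undirected bond (both directed copies share the row)."""
    out = np.zeros((graph.n_edges, len(BOND_ORDERS)), dtype=np.float64)
    for i, order in enumerate(graph.bond_orders):
        out[i, BOND_ORDERS.index(order)] = 1.0
    return out


def to_smiles(sequence: str) -> str:
    """Canonical SMILES export of the linear peptide (debugging aid)."""
    return sequence_to_peptide_graph(sequence, featurize=False).smiles


def dump_edge_list(graph: MolecularGraph) -> str:
    """Plain-text edge-list dump for inspection: `u v order` per line."""
    lines = [f"# atoms: {' '.join(graph.atom_elements)}"]
    for (u, v), order in zip(graph.edges, graph.bond_orders):
        lines.append(f"{u} {v} {order}")
    return "\n".join(lines) + "\n"
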