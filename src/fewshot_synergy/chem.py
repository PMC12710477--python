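"""Molecular graphs with a fixed 78-dimensional atom featurization.

Drugs are represented as heavy-atom undirected graphs whose nodes carry a
78-dimensional feature vector: one-hot element symbol over 44 slots (43 common
elements plus a reserved "other"), one-hot heavy-neighbor count (0-10),
one-hot implicit valence (0-10), one-hot total hydrogen count (0-10), and a
single aromaticity bit (44 + 11 + 11 + 11 + 1 = 78). Hydrogens are implicit:
they never become nodes, their count is a node feature. Bonds contribute
connectivity only; every edge carries weight 1 by default.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np

try:
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.*")
except ImportError:  # pragma: no cover - rdkit is a hard dependency
    Chem = None

ELEMENTS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb",
]
OTHER_SLOT = len(ELEMENTS)  # 43
N_SYMBOL = len(ELEMENTS) + 1  # 44
COUNT_MAX = 10  # one-hot blocks cover 0..10
N_COUNT = COUNT_MAX + 1
N_FEATURES = N_SYMBOL + 3 * N_COUNT + 1  # 78


@dataclass(frozen=True)
class AtomRecord:
    """The five atom descriptors the featurization consumes."""

    symbol: str
    degree: int  # heavy-atom neighbor count
    implicit_valence: int
    num_hydrogens: int  # total bonded hydrogens
    aromatic: bool


@dataclass
class MolecularGraph:
    """Heavy-atom graph of one drug.

    ``edges`` stores each bond in both directions (symmetric closure), with
    aligned nonnegative ``edge_weights``. Self-loops are forbidden; the
    self-contribution of graph convolution is added inside the layer.
    """

    drug_id: str
    node_features: np.ndarray  # (n_atoms, 78)
    edges: list = field(default_factory=list)  # [(u, v), ...] both directions
    edge_weights: list = field(default_factory=list)

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        if self.node_features.ndim != 2 or self.node_features.shape[1] != N_FEATURES:
            raise ValueError(
                f"node_features must be (n_atoms, {N_FEATURES}), "
                f"got {self.node_features.shape}"
            )
        if not self.edge_weights:
            self.edge_weights = [1.0] * len(self.edges)
        if len(self.edge_weights) != len(self.edges):
            raise ValueError("edge_weights must align with edges")
        n = self.n_atoms
        seen = {}
        for (u, v), w in zip(self.edges, self.edge_weights):
            if u == v:
                raise ValueError(f"self-loop on atom {u} is not allowed")
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u},{v}) out of range for {n} atoms")
            if w < 0:
                raise ValueError("edge weights must be nonnegative")
            seen[(u, v)] = w
        for (u, v), w in list(seen.items()):
            if (v, u) not in seen:  # canonicalize to symmetric closure
                seen[(v, u)] = w
        order = sorted(seen)
        self.edges = order
        self.edge_weights = [seen[e] for e in order]

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return len(self.edges) // 2

    def weighted_adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms))
        for (u, v), w in zip(self.edges, self.edge_weights):
            a[u, v] = w
        return a

    def norm_adjacency(self) -> np.ndarray:
        """Symmetric-normalized adjacency with self terms.

        Entry (u, v) is e_{v,u} / sqrt(D_v * D_u) for neighbors and the self
        slot, where D_u = 1 + sum of incident edge weights; this is the
        constant aggregation matrix of the graph convolution layer.
        """
        a = self.weighted_adjacency()
        d = 1.0 + a.sum(axis=1)
        a = a + np.eye(self.n_atoms)
        inv = 1.0 / np.sqrt(d)
        return inv[:, None] * a * inv[None, :]

    def permuted(self, perm) -> "MolecularGraph":
        """Relabel atoms by ``perm`` (new index = perm[old index])."""
        perm = list(perm)
        inv = np.empty(self.n_atoms, dtype=int)
        for old, new in enumerate(perm):
            inv[new] = old
        return MolecularGraph(
            drug_id=self.drug_id,
            node_features=self.node_features[inv],
            edges=[(perm[u], perm[v]) for u, v in self.edges],
            edge_weights=list(self.edge_weights),
        )


def _one_hot(value: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[min(value, size - 1)] = 1.0  # counts beyond the block clamp to the top slot
    return v


def featurize_atom(atom: AtomRecord) -> np.ndarray:
    """78-vector: symbol | degree | implicit valence | H count | aromatic."""
    for name in ("degree", "implicit_valence", "num_hydrogens"):
        if getattr(atom, name) < 0:
            raise ValueError(f"{name} must be nonnegative, got {getattr(atom, name)}")
    sym = np.zeros(N_SYMBOL)
    try:
        sym[ELEMENTS.index(atom.symbol)] = 1.0
    except ValueError:
        sym[OTHER_SLOT] = 1.0
    return np.concatenate(
        [
            sym,
            _one_hot(atom.degree, N_COUNT),
            _one_hot(atom.implicit_valence, N_COUNT),
            _one_hot(atom.num_hydrogens, N_COUNT),
            [1.0 if atom.aromatic else 0.0],
        ]
    )


def atom_record(atom) -> AtomRecord:
    """Descriptor record from an RDKit atom."""
    return AtomRecord(
        symbol=atom.GetSymbol(),
        degree=atom.GetDegree(),
        implicit_valence=atom.GetImplicitValence(),
        num_hydrogens=atom.GetTotalNumHs(),
        aromatic=atom.GetIsAromatic(),
    )


def graph_from_mol(mol, drug_id: str) -> MolecularGraph:
    if mol.GetNumAtoms() == 0:
        raise ValueError(f"record {drug_id!r} has zero heavy atoms")
    feats = np.stack([featurize_atom(atom_record(a)) for a in mol.GetAtoms()])
    edges = []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges += [(u, v), (v, u)]
    return MolecularGraph(drug_id=drug_id, node_features=feats, edges=edges)


def graph_from_smiles(smiles: str, drug_id: str) -> MolecularGraph:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES for {drug_id!r}: {smiles!r}")
    return graph_from_mol(mol, drug_id)


def parse_structures(path: str, format: str | None = None):
    """Parse an SDF or two-column (drug_id, smiles) file into graphs.

    Returns ``(graphs, failures)`` where failures is a list of
    ``(drug_id, reason)`` for records that could not be converted.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "sdf" if path.lower().endswith(".sdf") else "smiles"
    if format not in ("sdf", "smiles"):
        raise ValueError(f"unknown structure format {format!r}")

    graphs, failures = [], []
    if format == "smiles":
        with open(path) as fh:
            rows = [ln.split() for ln in fh if ln.strip() and not ln.startswith("#")]
        if not rows:
            raise ValueError(f"empty structure file: {path}")
        for row in rows:
            if len(row) < 2:
                failures.append((row[0] if row else "?", "missing smiles column"))
                continue
            drug_id, smi = row[0], row[1]
            try:
                graphs.append(graph_from_smiles(smi, drug_id))
            except ValueError as exc:
                warnings.warn(str(exc))
                failures.append((drug_id, str(exc)))
    else:
        supplier = Chem.SDMolSupplier(path, sanitize=True)
        n_records = 0
        for i, mol in enumerate(supplier):
            n_records += 1
            if mol is None:
                failures.append((f"record_{i}", "rdkit failed to parse record"))
                continue
            drug_id = (
                mol.GetProp("_Name")
                if mol.HasProp("_Name") and mol.GetProp("_Name")
                else f"record_{i}"
            )
            try:
                graphs.append(graph_from_mol(mol, drug_id))
            except ValueError as exc:
                warnings.warn(str(exc))
                failures.append((drug_id, str(exc)))
        if n_records == 0:
            raise ValueError(f"empty structure file: {path}")
    return graphs, failures
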