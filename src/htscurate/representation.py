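"""Molecular graph construction: 28-dim atom features, 2D and 3D graphs.

Atoms are nodes carrying a fixed 28-slot feature vector; the 2D graph
takes covalent bonds as edges, the 3D graph connects every atom pair
within a Euclidean distance cutoff (default 6 Å, chosen to be robust to
conformational flexibility).  Heavy atoms only by default — hydrogens
are folded into the attached-H feature.

The 28-slot node feature schema (versioned as ``ATOM_SCHEMA_VERSION``):

====== ===========================================================
slots  meaning
====== ===========================================================
0-10   element one-hot: C N O F P S Cl Br I B other
11-16  heavy-atom degree one-hot: 0 1 2 3 4 5+
17-19  formal charge one-hot: negative, zero, positive
20-24  hybridization one-hot: S SP SP2 SP3 other
25     aromaticity flag
26     total attached hydrogen count
27     ring-membership flag
====== ===========================================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chem import parse_smiles
from .types import CompoundRecord

ATOM_SCHEMA_VERSION = "1"
N_ATOM_FEATURES = 28

_ELEMENTS = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I", "B")
_HYBRIDIZATIONS = (
    Chem.HybridizationType.S,
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
)


@dataclass(frozen=True)
class GraphConfig:
    """Graph-construction settings.

    ``distance_cutoff`` (Å) bounds 3D edges; the boundary counts as an
    edge (closed interval).  ``include_hydrogens`` keeps explicit
    hydrogens as graph nodes.
    """

    distance_cutoff: float = 6.0
    include_hydrogens: bool = False

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be positive")


@dataclass
class MolGraph:
    """A molecular graph with per-node features.

    ``edges`` are undirected index pairs (i < j), without self-loops or
    duplicates; ``positions`` (n_atoms x 3, Å) is present iff
    ``dimensionality == "3D"``.
    """

    node_features: np.ndarray
    edges: list[tuple[int, int]]
    dimensionality: str
    edge_features: np.ndarray | None = None
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.node_features.ndim != 2 \
                or self.node_features.shape[1] != N_ATOM_FEATURES:
            raise ValueError(f"node features must be n x {N_ATOM_FEATURES}")
        n = self.node_features.shape[0]
        seen = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-loop")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("edge index out of range")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError("duplicate edge")
            seen.add(key)
        if self.dimensionality == "3D":
            if self.positions is None or self.positions.shape != (n, 3):
                raise ValueError("3D graphs need n x 3 positions")
        elif self.dimensionality != "2D":
            raise ValueError("dimensionality must be '2D' or '3D'")

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]


def _mol_from_record(record: CompoundRecord | str, config: GraphConfig):
    smiles = record.smiles if isinstance(record, CompoundRecord) else record
    mol, err = parse_smiles(smiles)
    if mol is None:
        raise ValueError(f"cannot build graph: {err} for {smiles!r}")
    if config.include_hydrogens:
        mol = Chem.AddHs(mol)
    return mol


def _atom_row(atom) -> np.ndarray:
    row = np.zeros(N_ATOM_FEATURES)
    sym = atom.GetSymbol()
    if sym in _ELEMENTS:
        row[_ELEMENTS.index(sym)] = 1.0
    else:
        row[10] = 1.0
        warnings.warn(f"element {sym} outside the feature schema; "
                      "mapped to the 'other' slot")
    row[11 + min(atom.GetDegree(), 5)] = 1.0
    charge = atom.GetFormalCharge()
    row[17 + (0 if charge < 0 else (1 if charge == 0 else 2))] = 1.0
    hyb = atom.GetHybridization()
    row[20 + (_HYBRIDIZATIONS.index(hyb) if hyb in _HYBRIDIZATIONS else 4)] = 1.0
    row[25] = 1.0 if atom.GetIsAromatic() else 0.0
    row[26] = float(atom.GetTotalNumHs())
    row[27] = 1.0 if atom.IsInRing() else 0.0
    return row


def atom_feature_matrix(record: CompoundRecord | str,
                        config: GraphConfig | None = None) -> np.ndarray:
    """The n_atoms x 28 node feature matrix for a molecule."""
    if config is None:
        config = GraphConfig()
    mol = _mol_from_record(record, config)
    return np.stack([_atom_row(a) for a in mol.GetAtoms()])


#: Edge feature slots: bond-type one-hot (single, double, triple,
#: aromatic), then a ring-membership flag.
N_BOND_FEATURES = 5
_BOND_TYPES = (
    Chem.BondType.SINGLE, Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE, Chem.BondType.AROMATIC,
)


def build_graph_2d(record: CompoundRecord | str,
                   config: GraphConfig | None = None) -> MolGraph:
    """Bond-connectivity graph: one undirected edge per covalent bond.

    Rejects disconnected (multi-component) inputs — mixtures must be
    resolved by curation first.
    """
    if config is None:
        config = GraphConfig()
    mol = _mol_from_record(record, config)
    if len(Chem.GetMolFrags(mol)) > 1:
        raise ValueError("disconnected molecule; resolve mixtures before "
                         "building graphs")
    features = np.stack([_atom_row(a) for a in mol.GetAtoms()])
    edges = []
    edge_rows = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((min(i, j), max(i, j)))
        row = np.zeros(N_BOND_FEATURES)
        btype = bond.GetBondType()
        if btype in _BOND_TYPES:
            row[_BOND_TYPES.index(btype)] = 1.0
        row[4] = 1.0 if bond.IsInRing() else 0.0
        edge_rows.append(row)
    return MolGraph(
        node_features=features,
        edges=edges,
        dimensionality="2D",
        edge_features=np.stack(edge_rows) if edge_rows else np.zeros((0, N_BOND_FEATURES)),
    )


def build_graph_3d(record: CompoundRecord | str, coordinates,
                   config: GraphConfig | None = None) -> MolGraph:
    """Distance-cutoff graph: an edge iff two atoms lie within cutoff Å.

    ``coordinates`` must be an n_atoms x 3 array matching the heavy-atom
    count of the record; positions are stored verbatim.  Atoms exactly
    at the cutoff are connected (closed interval).
    """
    if config is None:
        config = GraphConfig()
    mol = _mol_from_record(record, config)
    coords = np.asarray(coordinates, dtype=float)
    if coords.shape != (mol.GetNumAtoms(), 3):
        raise ValueError(
            f"coordinate shape {coords.shape} does not match atom count "
            f"{mol.GetNumAtoms()}")
    features = np.stack([_atom_row(a) for a in mol.GetAtoms()])
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    n = coords.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    within = dist[iu, ju] <= config.distance_cutoff
    edges = [(int(i), int(j)) for i, j in zip(iu[within], ju[within])]
    return MolGraph(
        node_features=features,
        edges=edges,
        dimensionality="3D",
        positions=coords.copy(),
    )
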