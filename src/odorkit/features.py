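"""Molecular featurization: circular/MACCS fingerprints, physicochemical
descriptors, and molecular graphs.

Feature vectors are a pure function of the molecule: any SMILES spelling of
the same structure yields bit-identical output. ECFP naming follows the
diameter convention (ECFP4 = Morgan radius 2, ECFP6 = radius 3), hashed to
1024 presence bits; MACCS is the standard 167-key set. The physicochemical
block is [molecular weight g/mol, Crippen logP, TPSA A^2, Crippen molar
refractivity] and is appended raw — standardization (train statistics only)
happens inside model pipelines to avoid leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, MACCSkeys, rdFingerprintGenerator

from .registry import SmilesParseError

SCHEMES = ("ecfp4", "ecfp6", "maccs")

_N_BITS = {"ecfp4": 1024, "ecfp6": 1024, "maccs": 167}
_RADIUS = {4: 2, 6: 3}

_GENERATORS = {
    d: rdFingerprintGenerator.GetMorganGenerator(radius=r, fpSize=1024)
    for d, r in _RADIUS.items()
}


@dataclass(frozen=True)
class FeatureBlock:
    """Fingerprint bits concatenated with the 4-descriptor physchem block."""

    scheme: str
    bits: np.ndarray
    physchem: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.bits, self.physchem])


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def ecfp(smiles: str, diameter: int = 4, nbits: int = 1024) -> np.ndarray:
    """Extended-connectivity fingerprint (diameter 4 or 6), folded to presence bits."""
    if diameter not in _RADIUS:
        raise ValueError(f"diameter must be 4 or 6, got {diameter}")
    gen = (
        _GENERATORS[diameter]
        if nbits == 1024
        else rdFingerprintGenerator.GetMorganGenerator(radius=_RADIUS[diameter], fpSize=nbits)
    )
    fp = gen.GetFingerprint(_mol(smiles))
    arr = np.zeros(nbits, dtype=np.uint8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr


def maccs(smiles: str) -> np.ndarray:
    """MACCS structural keys, 167 presence bits (key 0 is a placeholder)."""
    fp = MACCSkeys.GenMACCSKeys(_mol(smiles))
    arr = np.zeros(167, dtype=np.uint8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr


def physchem(smiles: str) -> np.ndarray:
    """[MW g/mol, logP, TPSA A^2, molar refractivity] as float64."""
    mol = _mol(smiles)
    return np.array(
        [
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            Descriptors.TPSA(mol),
            Crippen.MolMR(mol),
        ],
        dtype=np.float64,
    )


def featurize(smiles: str, scheme: str = "ecfp4") -> FeatureBlock:
    """Fingerprint bits + physchem block for one molecule.

    Total length is 1028 for ECFP schemes and 171 for MACCS.
    """
    scheme = scheme.lower()
    if scheme == "ecfp4":
        bits = ecfp(smiles, 4)
    elif scheme == "ecfp6":
        bits = ecfp(smiles, 6)
    elif scheme == "maccs":
        bits = maccs(smiles)
    else:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    return FeatureBlock(scheme=scheme, bits=bits, physchem=physchem(smiles))


def feature_matrix(smiles_list, scheme: str = "ecfp4") -> np.ndarray:
    """Stacked feature vectors, one row per molecule."""
    return np.stack([featurize(s, scheme).vector for s in smiles_list])


# ---------------------------------------------------------------------------
# Molecular graphs (for the graph-convolution model family)
# ---------------------------------------------------------------------------

#: Elements covered by the one-hot atom encoding; anything else shares a
#: trailing "other" slot. Chosen to span the elements common in volatiles.
GRAPH_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "P")


@dataclass(frozen=True)
class MolecularGraph:
    """Heavy-atom graph: one-hot element + degree + aromatic flag per node,
    undirected bonds stored once with their bond order, and the molecule's
    physchem 4-vector for readout concatenation."""

    node_features: np.ndarray  # (n_atoms, len(GRAPH_ELEMENTS) + 3)
    edges: np.ndarray  # (n_bonds, 2) atom indices, i < j
    bond_orders: np.ndarray  # (n_bonds,)
    physchem: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


def to_graph(smiles: str) -> MolecularGraph:
    """Build the heavy-atom molecular graph for one SMILES."""
    mol = _mol(smiles)
    n_el = len(GRAPH_ELEMENTS)
    feats = np.zeros((mol.GetNumAtoms(), n_el + 3), dtype=np.float64)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        sym = atom.GetSymbol()
        feats[i, GRAPH_ELEMENTS.index(sym) if sym in GRAPH_ELEMENTS else n_el] = 1.0
        feats[i, n_el + 1] = atom.GetDegree()
        feats[i, n_el + 2] = float(atom.GetIsAromatic())
    edges, orders = [], []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((min(a, b), max(a, b)))
        orders.append(bond.GetBondTypeAsDouble())
    edges_arr = np.array(edges, dtype=np.int64).reshape(-1, 2)
    return MolecularGraph(
        node_features=feats,
        edges=edges_arr,
        bond_orders=np.array(orders, dtype=np.float64),
        physchem=physchem(smiles),
    )
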