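"""SMILES -> molecular graphs with 75-dimensional atom features.

Drugs are modelled as heavy-atom graphs: nodes are non-hydrogen atoms, edges
are covalent bonds (binary, order-agnostic).  Each atom carries the standard
75-length ConvMol-style feature vector:

====================  =====  =========================================
block                 width  encoding
====================  =====  =========================================
atom symbol            44    one-hot over ATOM_SYMBOLS ('Unknown' last)
degree                 11    one-hot 0..10, overflow -> last bucket
implicit valence        7    one-hot 0..6, overflow -> last bucket
formal charge           1    signed integer as float
radical electrons       1    count as float
hybridization           5    one-hot SP, SP2, SP3, SP3D, SP3D2
aromaticity             1    flag
total hydrogens         5    one-hot 0..4, overflow -> last bucket
====================  =====  =========================================

The graph convolution consumes the symmetric-normalized adjacency with
self-loops, Â = D̃^{-1/2} (A + I) D̃^{-1/2}, built by
:func:`normalize_adjacency`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .exceptions import FeaturizationError, ValidationError

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.error")  # we raise our own errors with context

N_ATOM_FEATURES = 75

ATOM_SYMBOLS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg",
    "Na", "Ca", "Fe", "As", "Al", "I", "B", "V", "K", "Tl",
    "Yb", "Sb", "Sn", "Ag", "Pd", "Co", "Se", "Ti", "Zn", "H",
    "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn", "Zr", "Cr",
    "Pt", "Hg", "Pb", "Unknown",
]

_HYBRIDIZATIONS = [
    Chem.rdchem.HybridizationType.SP,
    Chem.rdchem.HybridizationType.SP2,
    Chem.rdchem.HybridizationType.SP3,
    Chem.rdchem.HybridizationType.SP3D,
    Chem.rdchem.HybridizationType.SP3D2,
]


def _one_hot(value, choices, overflow_to_last: bool = True) -> list[float]:
    vec = [0.0] * len(choices)
    if value in choices:
        vec[choices.index(value)] = 1.0
    elif overflow_to_last:
        vec[-1] = 1.0
    return vec


@dataclass
class MolecularGraph:
    """Heavy-atom graph of one drug: features X (n x 75), adjacency A (n x n)."""

    drug_id: str
    atom_features: np.ndarray
    adjacency: np.ndarray
    smiles: str = ""
    _normalized: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def normalized_adjacency(self) -> np.ndarray:
        if self._normalized is None:
            self._normalized = normalize_adjacency(self.adjacency)
        return self._normalized


def atom_features(atom: Chem.Atom) -> np.ndarray:
    """75-length feature vector for one heavy atom."""
    feats = (
        _one_hot(atom.GetSymbol(), ATOM_SYMBOLS)
        + _one_hot(atom.GetDegree(), list(range(11)))
        + _one_hot(atom.GetImplicitValence(), list(range(7)))
        + [float(atom.GetFormalCharge()), float(atom.GetNumRadicalElectrons())]
        + _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + _one_hot(atom.GetTotalNumHs(), list(range(5)))
    )
    return np.array(feats, dtype=np.float64)


def featurize_smiles(smiles: str, drug_id: str = "") -> MolecularGraph:
    """Parse a SMILES string into a featurized heavy-atom molecular graph.

    Multi-fragment SMILES (salts) are reduced to their largest fragment by
    heavy-atom count; the choice is logged.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES {smiles!r} (drug {drug_id or '?'})")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda f: f.GetNumAtoms())
        logger.info("SMILES %r has %d fragments; keeping largest", smiles, len(frags))
    n = mol.GetNumAtoms()
    if n == 0:
        raise FeaturizationError(f"SMILES {smiles!r} has no heavy atoms (drug {drug_id or '?'})")
    X = np.stack([atom_features(a) for a in mol.GetAtoms()])
    A = np.zeros((n, n), dtype=np.float64)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        A[i, j] = A[j, i] = 1.0
    return MolecularGraph(drug_id=drug_id, atom_features=X, adjacency=A, smiles=smiles)


def normalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops: D̃^{-1/2} (A + I) D̃^{-1/2}."""
    A = np.asarray(adjacency, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError(f"adjacency must be square, got shape {A.shape}")
    if not np.array_equal(A, A.T):
        raise ValidationError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValidationError("adjacency must have a zero diagonal (self-loops are added here)")
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def load_drug_library(path: str | Path) -> list[MolecularGraph]:
    """Read a drug_id,smiles CSV into featurized graphs (file order preserved)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    for col in ("drug_id", "smiles"):
        if col not in df.columns:
            raise ValidationError(f"{path}: drug library needs columns drug_id,smiles")
    if df.empty:
        logger.warning("%s: drug library is empty", path)
        return []
    seen: set[str] = set()
    graphs: list[MolecularGraph] = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        if row.drug_id in seen:
            raise ValidationError(f"{path} row {row_num}: duplicate drug_id {row.drug_id!r}")
        seen.add(row.drug_id)
        try:
            graphs.append(featurize_smiles(row.smiles, drug_id=row.drug_id))
        except FeaturizationError as exc:
            raise FeaturizationError(f"{path} row {row_num}: {exc}") from exc
    return graphs
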