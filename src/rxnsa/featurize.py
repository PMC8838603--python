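"""Molecular featurization for the three classifier families.

Three views of a molecule are produced: a 2048-bit ECFP4 fingerprint, the
six physicochemical descriptors (MW, TPSA, RTB, HBD, HBA, LogP) and a
molecular graph with 133-dimensional atom feature vectors plus bond
features, the input of the message-passing classifier.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .chem import ecfp4_bits, mol_from_smiles, physchem

ATOM_FEATURE_DIM = 133
BOND_FEATURE_DIM = 7

# 133 = 100 (atomic number) + 6 (degree) + 5 (formal charge) + 5 (H count)
# + 5 (hybridization) + 4 (chiral tag) + aromatic + in-ring + scaled mass
# + 5 padding flags (always zero)
_HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
)
_CHIRAL_TAGS = (
    Chem.ChiralType.CHI_UNSPECIFIED,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
    Chem.ChiralType.CHI_OTHER,
)
_BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)


@dataclass
class MolGraph:
    """Directed molecular graph: each bond contributes two directed edges."""

    atom_features: np.ndarray      # (n_atoms, 133)
    bond_features: np.ndarray      # (n_edges, 7)
    edge_src: np.ndarray           # (n_edges,) source atom index
    edge_dst: np.ndarray           # (n_edges,) destination atom index
    edge_rev: np.ndarray           # (n_edges,) index of the reverse edge


@dataclass
class FeatureBundle:
    ecfp: np.ndarray       # (2048,) in {0, 1}
    physchem: np.ndarray   # (6,)
    molgraph: MolGraph


def _one_hot_index(value: int, size: int, vec, offset: int) -> int:
    vec[offset + max(0, min(value, size - 1))] = 1.0
    return offset + size


def _one_hot_choice(value, choices: tuple, vec, offset: int) -> int:
    idx = choices.index(value) if value in choices else len(choices) - 1
    vec[offset + idx] = 1.0
    return offset + len(choices)


def atom_features(atom) -> np.ndarray:
    vec = np.zeros(ATOM_FEATURE_DIM, dtype=np.float64)
    off = _one_hot_index(atom.GetAtomicNum() - 1, 100, vec, 0)
    off = _one_hot_index(atom.GetDegree(), 6, vec, off)
    off = _one_hot_index(atom.GetFormalCharge() + 2, 5, vec, off)
    off = _one_hot_index(atom.GetTotalNumHs(), 5, vec, off)
    off = _one_hot_choice(atom.GetHybridization(), _HYBRIDIZATIONS, vec, off)
    off = _one_hot_choice(atom.GetChiralTag(), _CHIRAL_TAGS, vec, off)
    vec[off] = float(atom.GetIsAromatic()); off += 1
    vec[off] = float(atom.IsInRing()); off += 1
    vec[off] = atom.GetMass() / 100.0; off += 1
    assert off == 128  # remaining 5 dims are padding flags, always zero
    return vec


def bond_features(bond) -> np.ndarray:
    vec = np.zeros(BOND_FEATURE_DIM, dtype=np.float64)
    try:
        vec[_BOND_TYPES.index(bond.GetBondType())] = 1.0
    except ValueError:
        vec[3] = 1.0
    vec[4] = float(bond.GetIsConjugated())
    vec[5] = float(bond.IsInRing())
    vec[6] = 1.0  # bias/padding flag
    return vec


def mol_graph(smiles_or_mol) -> MolGraph:
    mol = (smiles_or_mol if isinstance(smiles_or_mol, Chem.Mol)
           else mol_from_smiles(smiles_or_mol))
    n = mol.GetNumAtoms()
    atoms = np.stack([atom_features(a) for a in mol.GetAtoms()]) if n else \
        np.zeros((0, ATOM_FEATURE_DIM))
    src, dst, feats = [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bf = bond_features(bond)
        src += [i, j]
        dst += [j, i]
        feats += [bf, bf]
    n_edges = len(src)
    rev = np.arange(n_edges) ^ 1 if n_edges else np.zeros(0, dtype=int)
    return MolGraph(
        atom_features=atoms,
        bond_features=(np.stack(feats) if feats
                       else np.zeros((0, BOND_FEATURE_DIM))),
        edge_src=np.array(src, dtype=int),
        edge_dst=np.array(dst, dtype=int),
        edge_rev=np.asarray(rev, dtype=int),
    )


def featurize(smiles: str) -> FeatureBundle:
    """All three molecular representations; deterministic per canonical SMILES."""
    mol = mol_from_smiles(smiles)
    return FeatureBundle(ecfp=ecfp4_bits(mol), physchem=physchem(mol),
                         molgraph=mol_graph(mol))
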