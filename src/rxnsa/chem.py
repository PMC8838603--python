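"""Substance identity, fingerprints and physicochemical descriptors.

A substance is identified by its canonical isomeric SMILES with atom-map
numbers stripped: stereochemistry is part of identity (it matters for how
hard a compound is to make), atom-map bookkeeping is not.
"""
from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator
from rdkit.DataStructs import TanimotoSimilarity

RDLogger.DisableLog("rdApp.*")

_ECFP4 = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


class ChemError(ValueError):
    """Raised when a SMILES string cannot be parsed or processed."""


@dataclass(frozen=True)
class Substance:
    """A chemical substance keyed by canonical isomeric SMILES (maps stripped)."""

    smiles: str
    key: str

    def __eq__(self, other):
        return isinstance(other, Substance) and self.key == other.key

    def __hash__(self):
        return hash(self.key)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str, strip_maps: bool = True) -> str:
    mol = mol_from_smiles(smiles)
    if strip_maps:
        for atom in mol.GetAtoms():
            atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol, isomericSmiles=True)


def substance_from_smiles(smiles: str) -> Substance:
    can = canonical_smiles(smiles)
    return Substance(smiles=can, key=can)


def ecfp4(smiles_or_mol):
    """2048-bit ECFP4 (Morgan radius-2) fingerprint."""
    mol = (smiles_or_mol if isinstance(smiles_or_mol, Chem.Mol)
           else mol_from_smiles(smiles_or_mol))
    return _ECFP4.GetFingerprint(mol)


def tanimoto(fp_a, fp_b) -> float:
    return TanimotoSimilarity(fp_a, fp_b)


def ecfp4_bits(smiles_or_mol):
    """ECFP4 as a numpy 0/1 vector of length 2048."""
    import numpy as np

    fp = ecfp4(smiles_or_mol)
    arr = np.zeros(2048, dtype=np.float64)
    arr[list(fp.GetOnBits())] = 1.0
    return arr


#: the six physicochemical descriptors used by the RF/DNN-PCD models
PHYSCHEM_NAMES = ("MW", "TPSA", "RTB", "HBD", "HBA", "LogP")


def physchem(smiles_or_mol):
    """MW, TPSA, rotatable bonds, H-bond donors/acceptors, Crippen LogP."""
    import numpy as np

    mol = (smiles_or_mol if isinstance(smiles_or_mol, Chem.Mol)
           else mol_from_smiles(smiles_or_mol))
    return np.array(
        [
            Descriptors.MolWt(mol),
            Descriptors.TPSA(mol),
            Descriptors.NumRotatableBonds(mol),
            Descriptors.NumHDonors(mol),
            Descriptors.NumHAcceptors(mol),
            Crippen.MolLogP(mol),
        ],
        dtype=np.float64,
    )


def mol_weight(smiles: str) -> float:
    return Descriptors.MolWt(mol_from_smiles(smiles))


def logp(smiles: str) -> float:
    return Crippen.MolLogP(mol_from_smiles(smiles))
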