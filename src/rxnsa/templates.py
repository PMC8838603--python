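"""Radius-bounded reaction template extraction and application.

A template is a pair of subgraph rewrite patterns (reaction SMARTS): the
forward pattern maps reactant fragments to product fragments, the inverse
pattern runs the rewrite backwards, from a product to predicted reactants.
The pattern covers the reaction center — every mapped atom whose bonding,
hydrogen count or charge changes between the two sides, plus atoms that
appear on only one side — extended by the atom environment within ``radius``
bonds and closed over multiply-bonded / charged neighbours so that adjacent
functional groups (carbonyls, nitro groups, ...) are never cut in half.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import Substance, mol_from_smiles
from .reaction_io import ReactionRecord

log = logging.getLogger(__name__)

_ORGANIC_AROMATIC = {"C", "N", "O", "S", "P", "B", "Se"}


class TemplateError(ValueError):
    """Template extraction failure; ``.code`` is machine-readable."""

    def __init__(self, code: str, msg: str = ""):
        super().__init__(msg or code)
        self.code = code


@dataclass(frozen=True)
class ReactionTemplate:
    """Forward and inverse rewrite patterns extracted at a given radius."""

    forward_pattern: str
    inverse_pattern: str
    radius: int = 1


def _atom_signature(atom):
    """Local signature used to detect bonding/H/charge changes of a mapped atom."""
    nbrs = []
    n_unmapped = 0
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        if other.GetAtomMapNum():
            nbrs.append((other.GetAtomMapNum(), bond.GetBondTypeAsDouble()))
        else:
            n_unmapped += 1
    return (atom.GetSymbol(), atom.GetFormalCharge(), tuple(sorted(nbrs)),
            n_unmapped, atom.GetTotalNumHs())


def _collect_mapped(mols):
    out = {}
    for i, mol in enumerate(mols):
        for atom in mol.GetAtoms():
            if atom.GetAtomMapNum():
                if atom.GetAtomMapNum() in out:
                    raise TemplateError("bad_atom_map",
                                        f"duplicate map {atom.GetAtomMapNum()}")
                out[atom.GetAtomMapNum()] = (i, atom)
    return out


def _center_maps(rmaps, pmaps):
    center = set()
    for mnum, (_, atom) in rmaps.items():
        if mnum not in pmaps:
            center.add(mnum)  # leaving atom
        elif _atom_signature(atom) != _atom_signature(pmaps[mnum][1]):
            center.add(mnum)
    center |= {m for m in pmaps if m not in rmaps}  # appearing atom
    return center


def _expand(mol, seed_idx, radius):
    """Seed atoms + radius-bond environment + multiple-bond/charge closure."""
    sel = set(seed_idx)
    for _ in range(radius):
        grown = set(sel)
        for i in sel:
            for nb in mol.GetAtomWithIdx(i).GetNeighbors():
                grown.add(nb.GetIdx())
        sel = grown
    changed = True
    while changed:
        changed = False
        for i in list(sel):
            for bond in mol.GetAtomWithIdx(i).GetBonds():
                other = bond.GetOtherAtom(mol.GetAtomWithIdx(i))
                if other.GetIdx() in sel:
                    continue
                if bond.GetBondTypeAsDouble() > 1.5 or other.GetFormalCharge():
                    sel.add(other.GetIdx())
                    changed = True
    return sel


def _query_symbol(atom):
    sym = atom.GetSymbol()
    if atom.GetIsAromatic() and sym in _ORGANIC_AROMATIC:
        sym = sym.lower()
    else:
        sym = f"#{atom.GetAtomicNum()}"
    q = (f"[{sym};H{atom.GetTotalNumHs()};D{atom.GetDegree()};"
         f"{atom.GetFormalCharge():+d}")
    if atom.GetAtomMapNum():
        q += f":{atom.GetAtomMapNum()}"
    return q + "]"


def _concrete_symbol(atom):
    sym = atom.GetSymbol()
    if atom.GetIsAromatic() and sym in _ORGANIC_AROMATIC:
        sym = sym.lower()
    out = f"[{sym}"
    n_h = atom.GetTotalNumHs()
    if n_h == 1:
        out += "H"
    elif n_h > 1:
        out += f"H{n_h}"
    charge = atom.GetFormalCharge()
    if charge:
        out += f"{charge:+d}" if abs(charge) > 1 else ("+" if charge > 0 else "-")
    if atom.GetAtomMapNum():
        out += f":{atom.GetAtomMapNum()}"
    return out + "]"


def _fragment(mol, sel, query: bool) -> str:
    symfn = _query_symbol if query else _concrete_symbol
    symbols = [symfn(a) for a in mol.GetAtoms()]
    smarts = Chem.MolFragmentToSmiles(
        mol, atomsToUse=sorted(sel), atomSymbols=symbols,
        allBondsExplicit=True, canonical=True)
    # disconnected selection within one molecule: keep as one component group
    return f"({smarts})" if "." in smarts else smarts


def extract_template(record: ReactionRecord, radius: int = 1) -> ReactionTemplate:
    """Extract the forward/inverse rewrite patterns of an atom-mapped record.

    Raises :class:`TemplateError` with code ``no_reaction_center`` when the
    two sides have identical mapped connectivity, or ``bad_atom_map`` when
    the mapping is inconsistent (duplicate maps, or no mapped product atom
    traceable to a reactant).
    """
    rmols = [mol_from_smiles(s) for s in
             record.mapped_reactants + record.mapped_agents]
    pmols = [mol_from_smiles(s) for s in record.mapped_products]
    rmaps = _collect_mapped(rmols)
    pmaps = _collect_mapped(pmols)
    if not (set(rmaps) & set(pmaps)):
        raise TemplateError("bad_atom_map", "no product atom traces to a reactant")
    center = _center_maps(rmaps, pmaps)
    if not center:
        raise TemplateError("no_reaction_center")

    r_sels: list[set | None] = []
    selected_maps: set[int] = set()
    for mol in rmols:
        seed = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() in center]
        contributes = any(a.GetAtomMapNum() in pmaps for a in mol.GetAtoms())
        if not seed and not contributes:
            r_sels.append(None)  # pure spectator (reagent) molecule
            continue
        sel = _expand(mol, seed, radius) if seed else set()
        # unmapped atoms of a contributing molecule are leaving-group atoms
        sel |= {a.GetIdx() for a in mol.GetAtoms() if not a.GetAtomMapNum()}
        r_sels.append(sel or None)
        selected_maps |= {mol.GetAtomWithIdx(i).GetAtomMapNum() for i in (sel or ())
                          if mol.GetAtomWithIdx(i).GetAtomMapNum()}

    p_sels = []
    for mol in pmols:
        seed = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() in center]
        sel = _expand(mol, seed, radius) if seed else set()
        sel |= {a.GetIdx() for a in mol.GetAtoms()
                if a.GetAtomMapNum() in selected_maps}
        p_sels.append(sel)
        selected_maps |= {mol.GetAtomWithIdx(i).GetAtomMapNum() for i in sel
                          if mol.GetAtomWithIdx(i).GetAtomMapNum()}

    # both sides must carry the same mapped-atom set where the maps exist
    for mol, sel in zip(rmols, r_sels):
        if sel is None:
            continue
        sel |= {a.GetIdx() for a in mol.GetAtoms()
                if a.GetAtomMapNum() in selected_maps}

    def build(mols, sels, query):
        return ".".join(_fragment(m, s, query)
                        for m, s in zip(mols, sels) if s)

    forward = build(rmols, r_sels, True) + ">>" + build(pmols, p_sels, False)
    inverse = build(pmols, p_sels, True) + ">>" + build(rmols, r_sels, False)
    return ReactionTemplate(forward_pattern=forward, inverse_pattern=inverse,
                            radius=radius)


def _run_rewrite(pattern: str, inputs: tuple) -> list[tuple[str, ...]]:
    rxn = AllChem.ReactionFromSmarts(pattern)
    if rxn.GetNumReactantTemplates() != len(inputs):
        return []
    results = []
    seen = set()
    for out_mols in rxn.RunReactants(inputs):
        smis = []
        ok = True
        for mol in out_mols:
            try:
                Chem.SanitizeMol(mol)
            except Exception:
                ok = False
                break
            for atom in mol.GetAtoms():
                atom.SetAtomMapNum(0)
            smis.append(Chem.MolToSmiles(mol, isomericSmiles=True))
        if not ok:
            continue
        key = tuple(sorted(smis))
        if key not in seen:
            seen.add(key)
            results.append(key)
    return sorted(results)


def apply_inverse(template: ReactionTemplate, product: Substance
                  ) -> list[list[Substance]]:
    """Run the inverse rewrite on a product; each result is one PR-set.

    An empty list means the template does not apply; application failures on
    individual matches are logged and skipped rather than raised.
    """
    try:
        prod = mol_from_smiles(product.smiles)
    except Exception:
        return []
    try:
        sets = _run_rewrite(template.inverse_pattern, (prod,))
    except Exception as exc:  # malformed pattern
        log.warning("inverse application failed on %s: %s", product.key, exc)
        return []
    return [[Substance(smiles=s, key=s) for s in smis] for smis in sets]


def apply_forward(template: ReactionTemplate, reactants: list[Substance]
                  ) -> list[list[Substance]]:
    """Run the forward rewrite on a reactant set (used for round-trip checks).

    Reactant order is matched against the pattern's template order; all
    permutations are tried so callers can pass an unordered set.
    """
    from itertools import permutations

    rxn = AllChem.ReactionFromSmarts(template.forward_pattern)
    n = rxn.GetNumReactantTemplates()
    if n > len(reactants):
        return []
    out, seen = [], set()
    for perm in permutations(reactants, n):
        mols = tuple(mol_from_smiles(s.smiles) for s in perm)
        try:
            for smis in _run_rewrite(template.forward_pattern, mols):
                if smis not in seen:
                    seen.add(smis)
                    out.append([Substance(smiles=s, key=s) for s in smis])
        except Exception:
            continue
    return out


def template_check(record: ReactionRecord, radius: int = 1) -> str | None:
    """filter_valid hook: returns the failure code, or None when extractable."""
    try:
        extract_template(record, radius)
        return None
    except TemplateError as exc:
        return exc.code
    except Exception:
        return "extraction_error"
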