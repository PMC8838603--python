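"""Parsing, deduplication and validity filtering of reaction-SMILES records.

Input files are plain text, one reaction per line, in the usual
``reactants>agents>products`` convention with optional tab-separated id and
source columns; ``#``-prefixed lines are comments.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

from rdkit import Chem

from .chem import ChemError, Substance, substance_from_smiles, mol_from_smiles


class ParseError(ValueError):
    pass


@dataclass
class ReactionRecord:
    """One parsed reaction with both canonical substances and mapped SMILES."""

    id: str
    reactants: list[Substance]
    agents: list[Substance]
    products: list[Substance]
    source: str = ""
    # atom-mapped per-species SMILES, parallel to the substance lists
    mapped_reactants: list[str] = field(default_factory=list)
    mapped_agents: list[str] = field(default_factory=list)
    mapped_products: list[str] = field(default_factory=list)
    role_warning: bool = False

    def reaction_smiles(self, mapped: bool = True) -> str:
        if mapped:
            parts = (self.mapped_reactants, self.mapped_agents, self.mapped_products)
        else:
            parts = ([s.smiles for s in self.reactants],
                     [s.smiles for s in self.agents],
                     [s.smiles for s in self.products])
        return ">".join(".".join(p) for p in parts)


def _parse_side(side: str, what: str, line_id: str):
    subs, mapped = [], []
    if side.strip():
        for smi in side.split("."):
            try:
                mol = mol_from_smiles(smi)
            except ChemError:
                raise ParseError(
                    f"record {line_id}: unparseable {what} species {smi!r}")
            mapped.append(Chem.MolToSmiles(mol, isomericSmiles=True))
            subs.append(substance_from_smiles(smi))
    return subs, mapped


def parse_reaction_smiles(line: str, id: str, source: str = "") -> ReactionRecord:
    """Parse one ``reactants>agents>products`` line into a record.

    Atom maps are preserved in the record's mapped SMILES; the substance
    lists are canonical and map-free.
    """
    fields = line.strip().split(">")
    if len(fields) != 3:
        raise ParseError(
            f"record {id}: expected 'reactants>agents>products', got {line!r}")
    reactants, m_reactants = _parse_side(fields[0], "reactant", id)
    agents, m_agents = _parse_side(fields[1], "agent", id)
    products, m_products = _parse_side(fields[2], "product", id)
    return ReactionRecord(
        id=id, reactants=reactants, agents=agents, products=products,
        source=source, mapped_reactants=m_reactants, mapped_agents=m_agents,
        mapped_products=m_products)


def read_reaction_file(path) -> list[ReactionRecord]:
    """Read a reaction-SMILES file (rxn_smiles [<TAB> id [<TAB> source]])."""
    records = []
    for i, raw in enumerate(Path(path).read_text().splitlines()):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        rid = cols[1] if len(cols) > 1 and cols[1] else f"r{i}"
        source = cols[2] if len(cols) > 2 else ""
        records.append(parse_reaction_smiles(cols[0], rid, source))
    return records


def write_reaction_file(records: Iterable[ReactionRecord], path) -> None:
    lines = [f"{r.reaction_smiles()}\t{r.id}\t{r.source}" for r in records]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _dedup_key(record: ReactionRecord):
    return (
        tuple(sorted(s.key for s in record.reactants)),
        tuple(sorted(s.key for s in record.agents)),
        tuple(sorted(s.key for s in record.products)),
    )


def deduplicate(records: list[ReactionRecord]) -> list[ReactionRecord]:
    """Drop records whose (reactants, agents, products) key multisets repeat.

    Component order and atom maps are ignored; the first occurrence wins and
    input order is otherwise preserved.
    """
    seen = set()
    out = []
    for rec in records:
        k = _dedup_key(rec)
        if k not in seen:
            seen.add(k)
            out.append(rec)
    return out


#: machine-readable rejection reasons emitted by filter_valid
REASONS = (
    "no_products",
    "no_reactants",
    "product_equals_reactant",
    "unmappable_product",
    "template_failure",
)


def _product_map_overlap(record: ReactionRecord) -> bool:
    """True when every product shares at least one atom map with a reactant."""
    reactant_maps = set()
    for smi in record.mapped_reactants + record.mapped_agents:
        mol = mol_from_smiles(smi)
        reactant_maps |= {a.GetAtomMapNum() for a in mol.GetAtoms()
                          if a.GetAtomMapNum()}
    for smi in record.mapped_products:
        mol = mol_from_smiles(smi)
        pmaps = {a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomMapNum()}
        if not (pmaps & reactant_maps):
            return False
    return True


def filter_valid(
    records: list[ReactionRecord],
    template_check: Callable[[ReactionRecord], str | None] | None = None,
):
    """Split records into (kept, rejected-with-reason).

    Rejection reasons: missing products, missing reactant side, a product
    repeating a reactant (self-loop), a product carrying no atom-map overlap
    with the reactant side, or — when a ``template_check`` callback is
    supplied by the downstream template stage — template extraction failure.
    """
    kept, rejected = [], []
    for rec in records:
        reason = None
        reactant_keys = {s.key for s in rec.reactants}
        if not rec.products:
            reason = "no_products"
        elif not rec.reactants and not rec.agents:
            reason = "no_reactants"
        elif any(p.key in reactant_keys for p in rec.products):
            reason = "product_equals_reactant"
        elif not _product_map_overlap(rec):
            reason = "unmappable_product"
        elif template_check is not None:
            err = template_check(rec)
            if err is not None:
                reason = f"template_failure:{err}"
        if reason is None:
            kept.append(rec)
        else:
            rejected.append((rec, reason))
    return kept, rejected


def write_rejected(rejected, path) -> None:
    """Side-car TSV of rejected records: reaction, id, reason."""
    lines = [f"{rec.reaction_smiles()}\t{rec.id}\t{reason}"
             for rec, reason in rejected]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
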