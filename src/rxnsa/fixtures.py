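"""Synthetic reaction corpora and molecule sets with known ground truth.

Every pipeline stage is testable without external data: the generator emits
layered, atom-mapped reaction corpora built from a closed set of reliable
coupling motifs (amide and ester formation between bifunctional monomers),
so the true reactant set, the reagents, and the shortest reaction path of
every substance are known by construction. Reagent injection reproduces the
classic corpus flaws — alkali metals, halide ions, Pd, solvents and mineral
acids misfiled in the reactant field — and duplicate records can be planted
at a chosen rate.

The chemistry is deliberately narrow: monomers are amino/hydroxy acids, so
each coupling product keeps one free head group (NH2 or OH) and one free
carboxylic acid and stays couplable at every depth. Fixtures exercise the
pipeline, not chemistry breadth.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem import canonical_smiles, mol_from_smiles
from .reaction_io import ReactionRecord, parse_reaction_smiles

CARBOXYL = Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]")
PRIMARY_AMINE = Chem.MolFromSmarts("[NX3;H2;+0;!$(NC=O)]")
ALCOHOL = Chem.MolFromSmarts("[OX2H1;+0;!$(OC=O)]")

#: Reagent library mirroring the flaw classes seen in patent reaction records:
#: alkali metals, halide ions, Pd, common solvents, mineral acids and bases.
REAGENT_LIBRARY = (
    "[Na]", "[K]", "[Li]", "[Br-]", "[I-]", "[Cl-]", "[Pd]",
    "ClCCl", "C1CCOC1", "CS(C)=O", "CC#N", "CO", "CCO",
    "Cl", "O=S(=O)(O)O", "[NH4+]", "ClB(Cl)Cl", "C[O-].[Na+]",
)


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a layered synthetic reaction corpus."""

    n_building_blocks: int = 20
    depth: int = 3
    branching: int = 2
    reagent_injection_rate: float = 0.0
    duplicate_rate: float = 0.0
    seed: int = 0

    def validate(self):
        if self.depth < 1:
            raise FixtureError("depth must be >= 1")
        if self.branching < 1 and self.depth > 1:
            raise FixtureError("branching 0 cannot reach depth > 1")
        for rate in (self.reagent_injection_rate, self.duplicate_rate):
            if not 0.0 <= rate <= 1.0:
                raise FixtureError("rates must lie in [0, 1]")
        if self.n_building_blocks < 2:
            raise FixtureError("need at least 2 building blocks")


@dataclass
class FixtureTruth:
    """Ground truth planted in a generated corpus."""

    roles: dict = field(default_factory=dict)      # id -> (reactant keys, reagent keys)
    srp: dict = field(default_factory=dict)        # key -> planted SRP (bb: 0)
    building_blocks: list = field(default_factory=list)
    n_base_records: int = 0
    n_duplicates: int = 0

    def to_json(self, path):
        from pathlib import Path

        payload = {
            "roles": {k: [sorted(v[0]), sorted(v[1])]
                      for k, v in self.roles.items()},
            "srp": self.srp,
            "building_blocks": self.building_blocks,
            "n_base_records": self.n_base_records,
            "n_duplicates": self.n_duplicates,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def monomer_library() -> list[str]:
    """Canonical SMILES of the bifunctional monomers (amino/hydroxy acids)."""
    bodies = []
    for length in range(1, 7):
        bodies.append("C" * length)
        for pos in range(length):
            bodies.append("".join("C(C)" if j == pos else "C"
                                  for j in range(length)))
        if length >= 2:
            for pos in range(length):
                bodies.append("".join("C(C)(C)" if j == pos else "C"
                                      for j in range(length)))
    bodies += ["Cc1ccc(cc1)", "CCc1ccc(cc1)", "Cc1cccc(c1)", "CCc1cccc(c1)"]
    out, seen = [], set()
    for head in ("N", "O"):
        for body in bodies:
            smi = head + body + "C(=O)O"
            try:
                can = canonical_smiles(smi)
            except Exception:
                continue
            if can not in seen:
                seen.add(can)
                out.append(can)
    return out


def _assign_maps(mol: Chem.Mol, start: int) -> int:
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(start)
        start += 1
    return start


def couple(acid_smiles: str, partner_smiles: str):
    """Condense an acid with its partner's head group (NH2 -> amide, OH -> ester).

    Returns (mapped reactant SMILES pair, mapped product SMILES, product key).
    """
    acid = mol_from_smiles(acid_smiles)
    partner = mol_from_smiles(partner_smiles)
    next_map = _assign_maps(acid, 1)
    _assign_maps(partner, next_map)

    carboxyl = acid.GetSubstructMatch(CARBOXYL)
    if not carboxyl:
        raise FixtureError(f"no carboxyl group in {acid_smiles}")
    amine = partner.GetSubstructMatch(PRIMARY_AMINE)
    site = amine[0] if amine else None
    if site is None:
        alcohol = partner.GetSubstructMatch(ALCOHOL)
        if not alcohol:
            raise FixtureError(f"no nucleophilic head in {partner_smiles}")
        site = alcohol[0]

    c_idx, _o_double, o_hydroxyl = carboxyl
    offset = acid.GetNumAtoms()
    editable = Chem.RWMol(Chem.CombineMols(acid, partner))
    editable.AddBond(c_idx, site + offset, Chem.BondType.SINGLE)
    editable.RemoveAtom(o_hydroxyl)
    product = editable.GetMol()
    Chem.SanitizeMol(product)

    mapped_reactants = (Chem.MolToSmiles(acid), Chem.MolToSmiles(partner))
    mapped_product = Chem.MolToSmiles(product)
    return mapped_reactants, mapped_product, canonical_smiles(mapped_product)


def generate_reaction_corpus(spec: FixtureSpec) -> tuple[list[str], FixtureTruth]:
    """Emit a layered reaction corpus as file lines plus its ground truth.

    Layer 0 holds the building blocks (planted SRP 0). Each layer-``l``
    product couples two layer-``l-1`` substances, so its planted SRP is
    ``l`` and equals 1 + min planted SRP of its true reactants. Reagents and
    duplicate records are injected at the spec's rates. Identical
    (spec, seed) pairs produce byte-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    library = monomer_library()
    if spec.n_building_blocks > len(library):
        raise FixtureError(
            f"at most {len(library)} building blocks available")
    idx = rng.choice(len(library), size=spec.n_building_blocks, replace=False)
    blocks = [library[i] for i in sorted(idx)]

    truth = FixtureTruth(building_blocks=list(blocks))
    truth.srp = {b: 0 for b in blocks}
    lines: list[str] = []
    rec_counter = 0
    prev_layer = list(blocks)

    for layer in range(1, spec.depth + 1):
        new_layer: list[str] = []
        n_products = len(prev_layer) * spec.branching
        made = set()
        for _slot in range(n_products):
            for _attempt in range(40):
                a = prev_layer[rng.integers(len(prev_layer))]
                b = prev_layer[rng.integers(len(prev_layer))]
                if a == b and len(prev_layer) > 1:
                    continue
                if (a, b) in made:
                    continue
                try:
                    (m_a, m_b), m_prod, prod_key = couple(a, b)
                except FixtureError:
                    continue
                if prod_key in (a, b):
                    continue
                made.add((a, b))
                break
            else:
                continue

            rec_id = f"fx{rec_counter}"
            rec_counter += 1
            reactant_side = [m_a, m_b]
            reagents = []
            if rng.random() < spec.reagent_injection_rate:
                n_inject = int(rng.integers(1, 3))
                for _ in range(n_inject):
                    reagents.append(
                        REAGENT_LIBRARY[rng.integers(len(REAGENT_LIBRARY))])
            mixed = reactant_side + reagents
            order = rng.permutation(len(mixed))
            rxn = ".".join(mixed[i] for i in order) + ">>" + m_prod
            lines.append(f"{rxn}\t{rec_id}\tUS-{rec_counter:06d}")
            truth.roles[rec_id] = (
                {canonical_smiles(a), canonical_smiles(b)},
                # dotted reagents (salt pairs) parse into separate species
                {canonical_smiles(comp) for r in reagents
                 for comp in r.split(".")},
            )
            planted = 1 + min(truth.srp[a], truth.srp[b])
            truth.srp[prod_key] = min(truth.srp.get(prod_key, planted), planted)
            assert truth.srp[prod_key] >= 1
            if prod_key not in new_layer and prod_key not in truth.building_blocks:
                new_layer.append(prod_key)

            if rng.random() < spec.duplicate_rate:
                dup_order = rng.permutation(len(mixed))
                dup_rxn = ".".join(mixed[i] for i in dup_order) + ">>" + m_prod
                dup_id = f"fx{rec_counter}"
                rec_counter += 1
                lines.append(f"{dup_rxn}\t{dup_id}\tUS-{rec_counter:06d}")
                truth.roles[dup_id] = truth.roles[rec_id]
                truth.n_duplicates += 1
        if not new_layer:
            raise FixtureError(f"layer {layer} produced no new substances")
        prev_layer = new_layer

    truth.n_base_records = rec_counter - truth.n_duplicates
    return lines, truth


def records_from_lines(lines: list[str]) -> list[ReactionRecord]:
    records = []
    for line in lines:
        cols = line.split("\t")
        records.append(parse_reaction_smiles(
            cols[0], cols[1] if len(cols) > 1 else f"r{len(records)}",
            cols[2] if len(cols) > 2 else ""))
    return records


def verify_pipeline_against_truth(lines: list[str], truth: FixtureTruth) -> dict:
    """Run the full pipeline on a generated corpus and score it against truth.

    Reports exact-set role recovery, SRP agreement with the planted values,
    starting-material recovery, and per-stage counts, as a JSON-able dict.
    """
    import math

    from .graph import build_graph, classify_nodes, compute_srp
    from .pipeline import designate_all_roles, prepare_records

    records = records_from_lines(lines)
    kept, rejected = prepare_records(records)
    with_roles, n_role_failures = designate_all_roles(kept)

    n_role_ok = n_role_total = 0
    for record, roles in with_roles:
        planted = truth.roles.get(record.id)
        if planted is None or roles is None:
            continue
        n_role_total += 1
        predicted = {s.key for s in roles.true_reactants}
        if predicted == planted[0]:
            n_role_ok += 1

    graph = build_graph(with_roles)
    typing = classify_nodes(graph, set(truth.building_blocks))
    srp = compute_srp(graph, typing)

    planted_products = {k: v for k, v in truth.srp.items() if v >= 1}
    n_srp_ok = 0
    for key, planted_srp in planted_products.items():
        got = srp.get(key, math.inf)
        if not math.isinf(got) and int(got) == planted_srp:
            n_srp_ok += 1

    recovered_sm = typing.starting_materials
    planted_sm = set(truth.building_blocks) & set(graph.nodes)
    return {
        "n_records_in": len(records),
        "n_records_kept": len(kept),
        "n_records_rejected": len(rejected),
        "rejections": {reason: sum(1 for _, r in rejected if r == reason)
                       for reason in sorted({r for _, r in rejected})},
        "n_role_failures": n_role_failures,
        "role_recovery": {
            "n_scored": n_role_total,
            "n_exact": n_role_ok,
            "accuracy": n_role_ok / n_role_total if n_role_total else None,
        },
        "srp_agreement": {
            "n_products": len(planted_products),
            "n_agree": n_srp_ok,
            "rate": n_srp_ok / len(planted_products) if planted_products else None,
        },
        "starting_materials": {
            "n_planted_in_graph": len(planted_sm),
            "n_recovered": len(recovered_sm & planted_sm),
            "n_spurious": len(recovered_sm - planted_sm),
        },
    }


# ---------------------------------------------------------------------------
# random abstract DAGs for shortest-path oracle tests
# ---------------------------------------------------------------------------

def generate_random_dag(n_nodes: int, n_edges: int, n_sources: int, seed: int):
    """Random layered DAG as a (MultiDiGraph, building-block key set) pair.

    Node keys are abstract strings; edges always point from a lower to a
    higher node index, so the graph is acyclic. The first ``n_sources``
    nodes get no incoming edges and form the purchasable set.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    graph = nx.MultiDiGraph()
    names = [f"m{i}" for i in range(n_nodes)]
    graph.add_nodes_from(names)
    added = 0
    while added < n_edges:
        u = int(rng.integers(0, n_nodes - 1))
        v = int(rng.integers(max(u + 1, n_sources), n_nodes))
        graph.add_edge(names[u], names[v], reaction_id=f"e{added}")
        added += 1
    return graph, set(names[:n_sources])


# ---------------------------------------------------------------------------
# molecule sets with planted classifier signal
# ---------------------------------------------------------------------------

_CORES = (
    "c1cc({x})ccc1{y}",
    "c1c({x})cc(C)cc1{y}",
    "C1CCC({x})CC1{y}",
    "c1cc({x})cnc1{y}",
    "c1ccc(-c2ccc({x})cc2)cc1{y}",
    "C({x})CCCC{y}",
    "c1c({x})cc(-c2ccc({y})cc2)cc1-c2ccccc2",
    "C({x})CCCCCCCC{y}",
    "c1cc2ccc({x})cc2cc1{y}",
    "c1cc({x})ccc1S(=O)(=O)Nc1ccc({y})cc1",
    "c1cc({x})ccc1C(=O)Oc1ccc({y})cc1",
)
_SUBSTITUENTS = (
    "C", "CC", "CCC", "CCCC", "CCCCC", "O", "OC", "OCC", "N", "NC",
    "F", "Cl", "Br", "I", "C(=O)O", "C(=O)OC", "C(=O)NC", "C#N", "C(F)(F)F",
    "CCO", "CC(C)C", "OCCC", "CCCCCC", "S", "SC",
    "Cc1ccccc1", "OCc1ccccc1", "C(=O)Oc1ccccc1", "N(CC)CC",
    "OCCOCC", "CCCCCCCC", "S(=O)(=O)NC", "C(F)(F)C(F)(F)F",
)
NITRO = "[N+](=O)[O-]"

# three-slot cores for the heavy end of the molecular-weight range
_CORES_HEAVY = (
    "c1c({x})cc(-c2ccc({y})cc2)cc1-c2ccc({z})cc2",
    "c1cc({x})ccc1C(=O)Oc1cc({z})cc({y})c1",
    "c1cc({x})ccc1C(=O)Nc1cc({z})cc({y})c1",
    "c1cc({x})ccc1OCC(=O)Nc1cc({y})ccc1{z}",
    "c1cc({x})ccc1S(=O)(=O)Nc1cc({y})ccc1{z}",
    "c1cc2ccc({x})cc2cc1C(=O)Oc1cc({y})ccc1{z}",
)


def molecule_pool(n: int, seed: int, with_nitro: bool | None = None,
                  heavy: bool = False) -> list[str]:
    """Sample up to ``n`` distinct valid molecules from the template grammar.

    ``with_nitro`` forces (True) or forbids (False) a planted nitro group;
    ``heavy`` restricts the draw to the large cores and substituents.
    """
    rng = np.random.default_rng(seed)
    if heavy:
        cores = _CORES_HEAVY
    elif with_nitro is not None:
        cores = _CORES + _CORES_HEAVY  # same scaffold pool for both classes
    else:
        cores = _CORES
    out, seen = [], set()
    attempts = 0
    while len(out) < n and attempts < n * 60:
        attempts += 1
        core = cores[rng.integers(len(cores))]
        slots = ["x", "y"] + (["z"] if "{z}" in core else [])
        fills = {s: _SUBSTITUENTS[rng.integers(len(_SUBSTITUENTS))]
                 for s in slots}
        if with_nitro:
            fills[slots[rng.integers(len(slots))]] = NITRO
        smi = core.format(**fills)
        try:
            can = canonical_smiles(smi)
        except Exception:
            continue
        if with_nitro is False and "[N+](=O)[O-]" in can:
            continue
        if can not in seen:
            seen.add(can)
            out.append(can)
    return out


def generate_model_fixture(n: int, signal: str, seed: int):
    """Balanced labeled molecule set with a planted, learnable signal.

    signal: ``descriptor-threshold`` (class 1 = MW below 300, class 0 = MW
    above 400, a separable gap), ``fingerprint-bit`` (class = value of the
    ECFP4 bit whose prevalence is closest to one half) or ``substructure``
    (class 1 = contains a nitro group).

    Returns (smiles list, labels 0/1 array, descriptor dict).
    """
    if n < 40:
        raise FixtureError("need n >= 40 for a meaningful fixture")
    half = n // 2
    rng = np.random.default_rng(seed)

    if signal == "substructure":
        pos = molecule_pool(half, seed, with_nitro=True)
        neg = molecule_pool(half, seed + 1, with_nitro=False)
        if len(pos) < half or len(neg) < half:
            raise FixtureError("molecule grammar too small for requested n")
        smiles = pos + neg
        labels = np.array([1] * half + [0] * half)
        descriptor = {"signal": "substructure", "pattern": NITRO}
    elif signal == "descriptor-threshold":
        from .chem import mol_weight

        pool = molecule_pool(3 * half, seed)
        pool_heavy = molecule_pool(3 * half, seed + 1, heavy=True)
        light = [s for s in pool if mol_weight(s) < 300][:half]
        seen = set(light)
        heavy = [s for s in pool + pool_heavy
                 if mol_weight(s) > 400 and s not in seen][:half]
        if len(light) < half or len(heavy) < half:
            raise FixtureError("not enough molecules on both sides of the MW gap")
        smiles = light + heavy
        labels = np.array([1] * half + [0] * half)
        descriptor = {"signal": "descriptor-threshold", "descriptor": "MW",
                      "low": 300, "high": 400}
    elif signal == "fingerprint-bit":
        from .chem import ecfp4_bits

        pool = molecule_pool(3 * half, seed)
        bits = np.stack([ecfp4_bits(s) for s in pool])
        prevalence = bits.mean(axis=0)
        bit = int(np.argmin(np.abs(prevalence - 0.5)))
        pos = [s for s, b in zip(pool, bits[:, bit]) if b > 0][:half]
        neg = [s for s, b in zip(pool, bits[:, bit]) if b == 0][:half]
        if len(pos) < half or len(neg) < half:
            raise FixtureError("no sufficiently balanced fingerprint bit")
        smiles = pos + neg
        labels = np.array([1] * half + [0] * half)
        descriptor = {"signal": "fingerprint-bit", "bit": bit}
    else:
        raise FixtureError(f"unknown signal {signal!r}")

    order = rng.permutation(len(smiles))
    smiles = [smiles[i] for i in order]
    labels = labels[order]
    return smiles, labels, descriptor


def generate_clustered_compounds(n_clusters: int, per_cluster: int, seed: int):
    """Compounds in planted structural clusters (halogen/homolog analog series).

    Returns (smiles list, cluster id list). Within-cluster ECFP4 Tanimoto is
    high (analog series share the scaffold); distinct scaffolds keep
    cross-cluster similarity low.
    """
    scaffolds = (
        "c1cc({x})ccc1C(=O)OCCc1ccccc1",
        "c1cc({x})ccc1NC(=O)C1CCCCC1",
        "C1CCC({x})CC1CCOC(=O)c1ccncc1",
        "c1cc({x})cnc1CC(=O)NCCN(C)C",
        "c1ccc(-c2ccc({x})cc2)cc1NC(=O)C(F)(F)F",
        "C({x})CCCCC(=O)NC1CCCC1",
        "c1cc({x})ccc1OCC(=O)N1CCOCC1",
        "C1CC({x})CCC1OC(=O)c1ccc(C#N)cc1",
        "c1cc({x})ccc1S(=O)(=O)NCCO",
        "c1cc({x})ccc1-n1cnc(C)c1",
        "C({x})COC(=O)C1CCOC1",
        "c1cc({x})cc2c1cccc2C(=O)O",
        "c1cc({x})ccc1C(=O)NC1CCN(C)CC1",
        "C1CC({x})CN1C(=O)OC(C)(C)C",
        "c1cc({x})ccc1CN1CCSC1=O",
        "c1cc({x})ccc1OC(F)F",
        "C({x})CCN(CC)S(=O)(=O)C",
        "c1cc({x})ccc1C(=O)Oc1ccccn1",
        "c1cc({x})sc1C(=O)NCc1ccco1",
        "C1CC({x})CCC1N1CCC(O)CC1",
        "c1cc({x})ccc1P(=O)(OC)OC",
        "c1cc({x})ccc1NC(=O)NC1CC1",
        "C({x})COCCOCC(=O)O",
        "c1cc({x})ccc1/C=C/C(=O)OC",
    )
    variants = ("F", "Cl", "Br", "I", "C")
    rng = np.random.default_rng(seed)
    if n_clusters > len(scaffolds):
        raise FixtureError(f"at most {len(scaffolds)} planted clusters")
    if per_cluster > len(variants):
        raise FixtureError(f"at most {len(variants)} members per cluster")
    picks = rng.permutation(len(scaffolds))[:n_clusters]
    smiles, cluster_ids = [], []
    for cid, pick in enumerate(picks):
        for var in variants[:per_cluster]:
            smiles.append(canonical_smiles(scaffolds[pick].format(x=var)))
            cluster_ids.append(cid)
    return smiles, cluster_ids
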