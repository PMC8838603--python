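"""Directed substance-level reaction network and shortest reaction paths.

Nodes are substances (canonical-SMILES keys); every true reactant of a
reaction gets a directed edge to every product of that reaction, tagged with
the reaction id. Reagents never enter the network. The shortest reaction
path (SRP) of a compound is the minimum number of directed edges from any
purchasable starting material to it.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .chem import logp as calc_logp, mol_weight
from .reaction_io import ReactionRecord
from .roles import RoleAssignment

log = logging.getLogger(__name__)

#: SRP value of a node no starting material reaches
UNREACHABLE = math.inf


@dataclass
class NodeTyping:
    """Terminal (never-a-product) vs normal (product) nodes, and which
    terminals are purchasable starting materials."""

    terminal: set = field(default_factory=set)
    normal: set = field(default_factory=set)
    starting_materials: set = field(default_factory=set)


def build_graph(records_with_roles: list[tuple[ReactionRecord, RoleAssignment | None]]
                ) -> nx.MultiDiGraph:
    """Build the substance network from role-designated records.

    Records whose role assignment failed (``None``) are skipped with a
    warning, as are self-loop edges that slipped through filtering. Each
    (reactant, product) pair of each reaction is one multi-edge keyed by the
    reaction id; the pair-level attribute ``weight`` counts the distinct
    source documents supporting the transformation.
    """
    graph = nx.MultiDiGraph()
    sources: dict[tuple[str, str], set] = {}
    smiles_of: dict[str, str] = {}
    for record, roles in records_with_roles:
        if roles is None:
            log.warning("record %s lacks role assignment; skipped", record.id)
            continue
        for reactant in roles.true_reactants:
            for product in record.products:
                if reactant.key == product.key:
                    log.warning("record %s: self-loop %s skipped",
                                record.id, reactant.key)
                    continue
                smiles_of[reactant.key] = reactant.smiles
                smiles_of[product.key] = product.smiles
                graph.add_edge(reactant.key, product.key, reaction_id=record.id)
                sources.setdefault((reactant.key, product.key), set()).add(
                    record.source or record.id)
    for (u, v), docs in sources.items():
        for k in graph[u][v]:
            graph[u][v][k]["weight"] = len(docs)
    nx.set_node_attributes(graph, smiles_of, "smiles")
    return graph


def classify_nodes(graph: nx.MultiDiGraph, building_blocks: set[str]) -> NodeTyping:
    """Partition nodes into terminal/normal; mark purchasable terminals."""
    typing = NodeTyping()
    for node in graph.nodes:
        if graph.in_degree(node) == 0 and graph.out_degree(node) >= 1:
            typing.terminal.add(node)
        elif graph.in_degree(node) >= 1:
            typing.normal.add(node)
    typing.starting_materials = typing.terminal & set(building_blocks)
    return typing


def filter_candidates(graph: nx.MultiDiGraph, typing: NodeTyping,
                      mw_range=(200.0, 500.0), logp_range=(0.0, 5.0)) -> set[str]:
    """Normal (product) nodes within the MW and LogP windows, bounds inclusive.

    Only label candidates are filtered; the graph keeps every node so that
    out-of-window substances still serve as path intermediates.
    """
    keep = set()
    for node in typing.normal:
        smiles = graph.nodes[node].get("smiles", node)
        try:
            mw = mol_weight(smiles)
            lp = calc_logp(smiles)
        except Exception:
            log.warning("property computation failed for %s; excluded", node)
            continue
        if mw_range[0] <= mw <= mw_range[1] and logp_range[0] <= lp <= logp_range[1]:
            keep.add(node)
    return keep


def compute_srp(graph: nx.MultiDiGraph, typing: NodeTyping,
                targets: set[str] | None = None) -> dict[str, float]:
    """Multi-source BFS step counts from the starting materials.

    Returns ``{key: steps}`` with :data:`UNREACHABLE` (inf) for nodes no
    starting material reaches. Edge multiplicity is irrelevant to path
    length, so the BFS runs on the simple projection.
    """
    if targets is None:
        targets = set(typing.normal)
    table = {t: UNREACHABLE for t in targets}
    if not typing.starting_materials:
        return table
    simple = nx.DiGraph(graph)
    dist = nx.multi_source_dijkstra_path_length(
        simple, typing.starting_materials & set(graph.nodes), weight=None)
    for t in targets:
        if t in dist and dist[t] > 0:
            table[t] = dist[t]
        elif t in dist and t in typing.starting_materials:
            table[t] = 0
    return table


def export_graphml(graph: nx.MultiDiGraph, path) -> None:
    """Write the network as GraphML (node attr: smiles; edge attrs:
    reaction_id, weight)."""
    nx.write_graphml(graph, path)


def import_graphml(path) -> nx.MultiDiGraph:
    g = nx.read_graphml(path, force_multigraph=True)
    return nx.MultiDiGraph(g)


def write_srp_table(table: dict[str, float], graph: nx.MultiDiGraph, path) -> None:
    """TSV of (key, smiles, srp); unreachable nodes print ``UNREACHABLE``."""
    from pathlib import Path

    lines = []
    for key in sorted(table):
        smiles = graph.nodes[key].get("smiles", key) if key in graph.nodes else key
        srp = "UNREACHABLE" if math.isinf(table[key]) else str(int(table[key]))
        lines.append(f"{key}\t{smiles}\t{srp}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
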