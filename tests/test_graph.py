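import math

import networkx as nx
import pytest

from rxnsa.chem import substance_from_smiles
from rxnsa.graph import (UNREACHABLE, build_graph, classify_nodes, compute_srp,
                         export_graphml, filter_candidates, import_graphml)
from rxnsa.roles import RoleAssignment


def _record(rid, reactant_smiles, product_smiles, source=""):
    from rxnsa.reaction_io import ReactionRecord

    reactants = [substance_from_smiles(s) for s in reactant_smiles]
    products = [substance_from_smiles(s) for s in product_smiles]
    rec = ReactionRecord(id=rid, reactants=reactants, agents=[],
                         products=products, source=source)
    roles = RoleAssignment(true_reactants=reactants, reagents=[])
    return rec, roles


def brute_force_srp(graph, sources, target):
    """Independent oracle: minimum over all simple paths, DFS with pruning."""
    best = math.inf
    simple = nx.DiGraph(graph)

    def dfs(node, depth, visited):
        nonlocal best
        if depth >= best:
            return
        if node == target:
            best = depth
            return
        for nxt in simple.successors(node):
            if nxt not in visited:
                visited.add(nxt)
                dfs(nxt, depth + 1, visited)
                visited.remove(nxt)

    for s in sources:
        if s in simple:
            dfs(s, 0, {s})
    return best


class TestBuild:
    def test_direct_construction(self):
        g = build_graph([_record("r1", ["CCO", "CBr"], ["CCOC"]),
                         _record("r2", ["CCOC"], ["CCOCC"])])
        assert set(g.nodes) == {"CCO", "CBr", "CCOC", "CCOCC"}
        assert g.has_edge("CCO", "CCOC") and g.has_edge("CCOC", "CCOCC")

    def test_edge_weight_counts_distinct_sources(self):
        g = build_graph([_record("r1", ["CCO"], ["CCBr"], source="US-1"),
                         _record("r2", ["CCO"], ["CCBr"], source="US-2")])
        weights = {d["weight"] for _, _, d in g.edges(data=True)}
        assert weights == {2}

    def test_self_loop_skipped_with_warning(self, caplog):
        g = build_graph([_record("r1", ["CCO"], ["CCO"])])
        assert g.number_of_edges() == 0

    def test_record_without_roles_skipped(self):
        rec, _ = _record("r1", ["CCO"], ["CCBr"])
        g = build_graph([(rec, None)])
        assert g.number_of_nodes() == 0

    def test_reagents_never_become_nodes(self, clean_corpus):
        from rxnsa.fixtures import FixtureSpec, generate_reaction_corpus, records_from_lines
        from rxnsa.pipeline import designate_all_roles, prepare_records

        spec = FixtureSpec(n_building_blocks=8, depth=2, branching=2,
                           reagent_injection_rate=1.0, seed=3)
        lines, truth = generate_reaction_corpus(spec)
        kept, _ = prepare_records(records_from_lines(lines))
        with_roles, _ = designate_all_roles(kept)
        g = build_graph(with_roles)
        reagent_keys = set().union(*(r[1] for r in truth.roles.values()))
        planted = set().union(*(r[0] for r in truth.roles.values()))
        assert not (set(g.nodes) & (reagent_keys - planted))


class TestTyping:
    def test_chain_partition(self):
        g = build_graph([_record("r1", ["CCO"], ["CCBr"]),
                         _record("r2", ["CCBr"], ["CCN"])])
        typing = classify_nodes(g, {"CCO"})
        assert typing.terminal == {"CCO"}
        assert typing.normal == {"CCBr", "CCN"}
        assert typing.starting_materials == {"CCO"}

    def test_terminal_not_in_blocks_is_not_starting(self):
        g = build_graph([_record("r1", ["CCO"], ["CCBr"])])
        typing = classify_nodes(g, {"CCCCO"})
        assert typing.terminal == {"CCO"} and not typing.starting_materials

    def test_partition_counts(self, clean_corpus):
        from rxnsa.fixtures import records_from_lines
        from rxnsa.pipeline import designate_all_roles, prepare_records

        kept, _ = prepare_records(records_from_lines(clean_corpus[0]))
        with_roles, _ = designate_all_roles(kept)
        g = build_graph(with_roles)
        typing = classify_nodes(g, set(clean_corpus[1].building_blocks))
        connected = {n for n in g.nodes
                     if g.in_degree(n) + g.out_degree(n) >= 1}
        assert typing.terminal | typing.normal == connected
        assert not (typing.terminal & typing.normal)


class TestCandidateFilter:
    def _graph(self):
        return build_graph([
            _record("r1", ["CCO"], ["c1ccccc1"]),                 # MW 78
            _record("r2", ["CCO"], ["CCCCCCCCCCc1ccc(O)cc1C#N"]),  # mid-range
        ])

    def test_light_molecule_excluded_midrange_included(self):
        g = self._graph()
        typing = classify_nodes(g, {"CCO"})
        kept = filter_candidates(g, typing, (200, 500), (0, 5))
        assert "c1ccccc1" not in kept
        assert len(kept) == 1

    def test_boundaries_inclusive(self):
        from rxnsa.chem import logp, mol_weight

        g = self._graph()
        typing = classify_nodes(g, {"CCO"})
        target = next(iter(filter_candidates(g, typing, (200, 500), (0, 5))))
        mw, lp = mol_weight(target), logp(target)
        assert filter_candidates(g, typing, (mw, mw + 1), (lp, lp + 1)) == {target}
        assert filter_candidates(g, typing, (mw - 1, mw), (lp - 1, lp)) == {target}


class TestSrp:
    def test_chain_length(self):
        g = nx.MultiDiGraph([("S", "A"), ("A", "B"), ("B", "C")])
        typing = classify_nodes(g, {"S"})
        srp = compute_srp(g, typing)
        assert srp["C"] == 3 and srp["A"] == 1

    def test_many_paths_minimum_three(self):
        """A product reachable by many routes takes the shortest: 19 distinct
        paths, minimum length 3."""
        g = nx.MultiDiGraph()
        # 3-step backbone S -> x1 -> x2 -> T
        g.add_edge("S", "x1"); g.add_edge("x1", "x2"); g.add_edge("x2", "T")
        # 18 longer routes: S -> a_i -> b_i -> c_i -> T (i = 0..17), lengths 4
        for i in range(18):
            g.add_edge("S", f"a{i}"); g.add_edge(f"a{i}", f"b{i}")
            g.add_edge(f"b{i}", f"c{i}"); g.add_edge(f"c{i}", "T")
        typing = classify_nodes(g, {"S"})
        n_paths = len(list(nx.all_simple_paths(nx.DiGraph(g), "S", "T")))
        assert n_paths == 19
        assert compute_srp(g, typing, {"T"})["T"] == 3

    def test_unreachable_marked(self):
        g = nx.MultiDiGraph([("S", "A"), ("Z", "B")])
        typing = classify_nodes(g, {"S"})
        srp = compute_srp(g, typing)
        assert srp["B"] == UNREACHABLE

    def test_matches_brute_force_on_random_dags(self):
        from rxnsa.fixtures import generate_random_dag

        for seed in range(5):
            g, blocks = generate_random_dag(60, 120, 8, seed=seed)
            typing = classify_nodes(g, blocks)
            srp = compute_srp(g, typing)
            for target in sorted(typing.normal):
                assert srp[target] == brute_force_srp(g, blocks, target)

    def test_triangle_inequality_on_every_edge(self, clean_report, clean_corpus):
        from rxnsa.fixtures import generate_random_dag

        g, blocks = generate_random_dag(150, 350, 15, seed=42)
        typing = classify_nodes(g, blocks)
        srp = compute_srp(g, typing, set(g.nodes))
        dist = dict(srp)
        for s in typing.starting_materials:
            dist[s] = 0
        for u, v in nx.DiGraph(g).edges:
            du = dist.get(u, math.inf)
            assert dist.get(v, math.inf) <= du + 1

    def test_removing_non_starting_terminal_never_shortens_paths(self):
        from rxnsa.fixtures import generate_random_dag

        g, blocks = generate_random_dag(80, 160, 10, seed=9)
        typing = classify_nodes(g, blocks)
        before = compute_srp(g, typing)
        victims = sorted(typing.terminal - typing.starting_materials)[:3]
        g2 = g.copy()
        g2.remove_nodes_from(victims)
        typing2 = classify_nodes(g2, blocks)
        after = compute_srp(g2, typing2)
        for node, srp_before in before.items():
            if node in after:
                assert after[node] >= srp_before

    def test_multi_source_equals_min_over_single_sources(self):
        from rxnsa.fixtures import generate_random_dag

        g, blocks = generate_random_dag(100, 250, 12, seed=5)
        typing = classify_nodes(g, blocks)
        multi = compute_srp(g, typing)
        simple = nx.DiGraph(g)
        for target in sorted(typing.normal):
            best = math.inf
            for s in blocks:
                try:
                    best = min(best, nx.shortest_path_length(simple, s, target))
                except nx.NetworkXNoPath:
                    pass
            assert multi[target] == best


class TestGraphML:
    def test_round_trip_preserves_structure(self, tmp_path):
        g = build_graph([_record("r1", ["CCO", "CBr"], ["CCOC"], "US-1"),
                         _record("r2", ["CCOC"], ["CCOCC"], "US-2"),
                         _record("r3", ["CCO", "CBr"], ["CCOC"], "US-3")])
        path = tmp_path / "g.graphml"
        export_graphml(g, path)
        g2 = import_graphml(path)
        assert set(g.nodes) == set(g2.nodes)
        assert sorted(g.edges()) == sorted(g2.edges())
        assert nx.is_isomorphic(g, g2)
        assert {g2.nodes[n]["smiles"] for n in g2.nodes} == set(g.nodes)

    def test_empty_graph_round_trips(self, tmp_path):
        path = tmp_path / "empty.graphml"
        export_graphml(nx.MultiDiGraph(), path)
        assert import_graphml(path).number_of_nodes() == 0

    def test_node_count_in_file(self, tmp_path):
        g = build_graph([_record("r1", ["CCO"], ["CCBr"])])
        path = tmp_path / "g.graphml"
        export_graphml(g, path)
        assert path.read_text().count("<node ") == g.number_of_nodes()
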