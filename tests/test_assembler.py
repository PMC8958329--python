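"""Seed selection, subgraph extension, the bottleneck DP, and the assembly loop."""

from __future__ import annotations

import random

import pytest

from spliceweave.assembler import (
    Seed,
    TranscriptPath,
    assemble_locus,
    extend_subgraph,
    path_to_transcript_exons,
    run_dp,
    select_seed,
    update_graph,
)
from spliceweave.labeled_graph import Label
from spliceweave.paired_paths import PairedPath
from spliceweave.splice_graph import ADJACENCY, JUNCTION

from conftest import chain_nodes, make_labeled_graph


def diamond_graph(label35=Label.L2_PLUS, label45=Label.L2_PLUS):
    n = chain_nodes(5)
    g = make_labeled_graph(
        {iv: 10.0 for iv in n},
        {
            (n[0], n[1]): (10.0, Label.L2_PLUS),
            (n[1], n[2]): (8.0, Label.L2_PLUS),
            (n[1], n[3]): (5.0, Label.L2_PLUS),
            (n[2], n[4]): (6.0, label35),
            (n[3], n[4]): (9.0, label45),
        },
    )
    return g, n


def edge_seed(g, key):
    return Seed("edge", key, g.edges[key].weight, g.edges[key].label)


class TestSelectSeed:
    def test_class_priority_beats_weight(self):
        g, n = diamond_graph()
        pp = [
            PairedPath(nodes=(n[0], n[1], n[2]), cov=5.0, label=Label.L2_PLUS),
            PairedPath(nodes=(n[0], n[1], n[3]), cov=9.0, label=Label.L2_PLUS),
            PairedPath(nodes=(n[1], n[2], n[4]), cov=50.0, label=Label.L2_MINUS),
        ]
        seed = select_seed(g, pp)
        assert seed.kind == "paired_path" and seed.cov == 9.0

    def test_falls_back_to_lower_label_paths(self):
        g, n = diamond_graph()
        pp = [
            PairedPath(nodes=(n[0], n[1], n[2]), cov=5.0, label=Label.L2_PLUS,
                       used=True),
            PairedPath(nodes=(n[1], n[2], n[4]), cov=2.0, label=Label.L2_MINUS),
        ]
        seed = select_seed(g, pp)
        assert seed.kind == "paired_path" and seed.label == Label.L2_MINUS

    def test_edges_seed_when_no_paths_exist(self):
        g, n = diamond_graph()
        seed = select_seed(g, [])
        assert seed.kind == "edge" and seed.cov == 10.0  # heaviest 2+ edge

    def test_none_when_everything_used_and_covered(self):
        g, _ = diamond_graph()
        for e in g.edges.values():
            e.covered = True
        assert select_seed(g, []) is None


class TestExtendSubgraph:
    def test_seed_at_chain_end_pulls_backward_cone(self):
        n = chain_nodes(4)
        g = make_labeled_graph(
            {iv: 1.0 for iv in n},
            {(n[i], n[i + 1]): (1.0, Label.L2_PLUS) for i in range(3)},
        )
        gs = extend_subgraph(g, edge_seed(g, (n[2], n[3])))
        assert gs.real_edges == set(g.edges)
        assert gs.origin_targets == [n[0]] and gs.dest_sources == [n[3]]

    def test_seed_at_diamond_entry_spans_whole_diamond(self):
        g, n = diamond_graph()
        gs = extend_subgraph(g, edge_seed(g, (n[0], n[1])))
        assert gs.real_edges == set(g.edges)

    def test_edge_entering_cone_from_outside_excluded(self):
        n = chain_nodes(4)
        g = make_labeled_graph(
            {iv: 1.0 for iv in n},
            {
                (n[0], n[1]): (1.0, Label.L2_PLUS),
                (n[1], n[2]): (1.0, Label.L2_PLUS),
                (n[3], n[2]): (1.0, Label.L2_PLUS),  # never forward of n[1]
            },
        )
        # note: (n[3], n[2]) is coordinate-backward here; rebuild properly
        g = make_labeled_graph(
            {iv: 1.0 for iv in n},
            {
                (n[0], n[1]): (1.0, Label.L2_PLUS),
                (n[1], n[3]): (1.0, Label.L2_PLUS),
                (n[2], n[3]): (1.0, Label.L2_PLUS),  # enters cone node n[3]
            },
        )
        gs = extend_subgraph(g, edge_seed(g, (n[0], n[1])))
        assert (n[2], n[3]) not in gs.real_edges

    def test_mid_diamond_seed_excludes_parallel_branch(self):
        g, n = diamond_graph()
        gs = extend_subgraph(g, edge_seed(g, (n[1], n[2])))
        assert (n[1], n[3]) not in gs.real_edges
        assert (n[3], n[4]) not in gs.real_edges


class TestRunDP:
    def test_uniform_labels_pick_widest_branch(self):
        g, n = diamond_graph()
        seed = edge_seed(g, (n[0], n[1]))
        path = run_dp(extend_subgraph(g, seed), seed, g)
        assert path.nodes == (n[0], n[1], n[2], n[4])
        assert path.f_min == 6.0  # min(10, 8, 6) beats min(10, 5, 9)

    def test_label_class_beats_expression(self):
        g, n = diamond_graph(label35=Label.L1, label45=Label.L2_PLUS)
        seed = edge_seed(g, (n[0], n[1]))
        path = run_dp(extend_subgraph(g, seed), seed, g)
        assert path.nodes == (n[0], n[1], n[3], n[4])
        assert path.f_min == 5.0

    def test_linear_chain_recovers_fully_from_any_seed(self):
        n = chain_nodes(5)
        weights = [7.0, 3.0, 9.0, 5.0]
        g = make_labeled_graph(
            {iv: 1.0 for iv in n},
            {(n[i], n[i + 1]): (weights[i], Label.L2_PLUS) for i in range(4)},
        )
        for key in list(g.edges):
            seed = edge_seed(g, key)
            path = run_dp(extend_subgraph(g, seed), seed, g)
            assert path.nodes == tuple(n)
            assert path.f_min == 3.0

    def test_paired_path_seed_contained_in_result(self):
        g, n = diamond_graph()
        seed = Seed("paired_path", (n[1], n[3], n[4]), 4.0, Label.L2_PLUS)
        path = run_dp(extend_subgraph(g, seed), seed, g)
        assert path.nodes == (n[0], n[1], n[3], n[4])


def _random_dag(rng, max_edges=12, labels=(Label.L2_PLUS,)):
    while True:
        n_nodes = rng.randint(4, 8)
        n = chain_nodes(n_nodes)
        edges = {}
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < 0.35:
                    edges[(n[i], n[j])] = (
                        rng.uniform(1, 100),
                        rng.choice(labels),
                    )
        if 1 <= len(edges) <= max_edges:
            return make_labeled_graph({iv: 1.0 for iv in n}, edges)


def _maximal_paths_through(g, seed_key):
    """Exhaustively enumerate source-to-sink paths containing the seed edge."""
    out_adj = {}
    in_deg = {iv: 0 for iv in g.nodes}
    for u, v in g.edges:
        out_adj.setdefault(u, []).append(v)
        in_deg[v] += 1
    linked = {iv for k in g.edges for iv in k}
    sources = [iv for iv in linked if in_deg[iv] == 0]
    paths = []

    def walk(node, acc):
        nxt = out_adj.get(node, [])
        if not nxt:
            paths.append(tuple(acc))
            return
        for v in nxt:
            walk(v, acc + [v])

    for s in sources:
        walk(s, [s])
    u, v = seed_key
    keep = []
    for p in paths:
        for i in range(len(p) - 1):
            if (p[i], p[i + 1]) == seed_key:
                keep.append(p)
                break
    return keep


def _bottleneck(g, path):
    return min(g.edges[(path[i], path[i + 1])].weight for i in range(len(path) - 1))


class TestBottleneckOptimality:
    @pytest.mark.parametrize("batch", range(4))
    def test_matches_exhaustive_enumeration(self, batch):
        # uniform labels: extracted bottleneck == max over all maximal paths
        # through the seed edge
        rng = random.Random(1000 + batch)
        for _ in range(50):
            g = _random_dag(rng)
            key = rng.choice(sorted(g.edges))
            seed = edge_seed(g, key)
            path = run_dp(extend_subgraph(g, seed), seed, g)
            candidates = _maximal_paths_through(g, key)
            assert candidates, "seed edge must lie on some maximal path"
            best = max(_bottleneck(g, p) for p in candidates)
            assert path.f_min == pytest.approx(best)
            assert path.nodes in candidates

    def test_mixed_labels_match_reference_simulation(self):
        rng = random.Random(77)
        checked = 0
        while checked < 50:
            g = _random_dag(rng, labels=(Label.L2_PLUS, Label.L2_MINUS, Label.L1))
            key = rng.choice(sorted(g.edges))
            seed = edge_seed(g, key)
            path = run_dp(extend_subgraph(g, seed), seed, g)
            assert path.nodes == _reference_extraction(g, seed)
            checked += 1


def _reference_extraction(g, seed):
    """Straightforward re-derivation of the label-prioritized rule, keyed by
    edge tuples instead of topological ids."""
    gs = extend_subgraph(g, seed)
    order = sorted(gs.nodes)
    pos = {v: i + 1 for i, v in enumerate(order)}
    pos["__o__"], pos["__d__"] = 0, len(order) + 1
    E = {}
    for u, v in gs.real_edges:
        E[(u, v)] = (g.edges[(u, v)].weight, g.edges[(u, v)].label)
    for v in gs.origin_targets:
        E[("__o__", v)] = (float("inf"), Label.L1)
    for u in gs.dest_sources:
        E[(u, "__d__")] = (float("inf"), Label.L1)
    ordered = sorted(E, key=lambda k: (pos[k[0]], pos[k[1]]))
    first = (seed.nodes[0], seed.nodes[1])
    last = (seed.nodes[-2], seed.nodes[-1])
    exp = {first: seed.cov, last: seed.cov}
    pre, suc = {}, {}
    fwd = {last}
    for k in ordered:
        if ordered.index(k) <= ordered.index(last):
            continue
        cands = [c for c in fwd if c[1] == k[0]]
        if not cands:
            continue
        best = max(
            cands, key=lambda c: (E[c][1], exp[c], [-pos[c[0]], -pos[c[1]]])
        )
        exp[k] = min(E[k][0], exp[best])
        pre[k] = best
        fwd.add(k)
    bwd = {first}
    for k in reversed(ordered):
        if ordered.index(k) >= ordered.index(first):
            continue
        cands = [c for c in bwd if c[0] == k[1]]
        if not cands:
            continue
        best = max(
            cands, key=lambda c: (E[c][1], exp[c], [-pos[c[0]], -pos[c[1]]])
        )
        exp[k] = min(E[k][0], exp[best])
        suc[k] = best
        bwd.add(k)
    dconn = [k for k in exp if k[1] == "__d__"]
    oconn = [k for k in exp if k[0] == "__o__"]
    d = max(dconn, key=lambda k: (exp[k], [-pos[k[0]], -pos[k[1]]]))
    o = max(oconn, key=lambda k: (exp[k], [-pos[k[0]], -pos[k[1]]]))
    chain = [d]
    while chain[-1] != last:
        chain.append(pre[chain[-1]])
    edges_after = list(reversed(chain))[1:]  # everything beyond the seed's last edge
    head = [o]
    while head[-1] != first:
        head.append(suc[head[-1]])
    seed_rest = [
        (seed.nodes[i], seed.nodes[i + 1]) for i in range(1, len(seed.nodes) - 1)
    ]
    full = head + seed_rest + edges_after
    nodes = [k[1] for k in full[:-1]]
    return tuple(nodes)


class TestUpdateAndLoop:
    def test_subtraction_zeroing_and_relabel(self):
        n = chain_nodes(4)
        g = make_labeled_graph(
            {iv: 1.0 for iv in n},
            {
                (n[0], n[1]): (6.0, Label.L2_PLUS),
                (n[1], n[2]): (8.0, Label.L2_PLUS),
                (n[2], n[3]): (10.0, Label.L2_PLUS),
            },
        )
        path = TranscriptPath(tuple(n), 6.0, Seed("edge", (n[0], n[1]), 6.0,
                                                  Label.L2_PLUS))
        update_graph(g, path, [])
        assert [g.edges[k].weight for k in sorted(g.edges)] == [0.0, 2.0, 4.0]
        assert g.edges[(n[0], n[1])].label == Label.L1
        assert all(e.covered for e in g.edges.values())

    def test_contained_paired_path_marked_used(self):
        n = chain_nodes(5)
        g = make_labeled_graph(
            {iv: 1.0 for iv in n},
            {(n[i], n[i + 1]): (5.0, Label.L2_PLUS) for i in range(4)},
        )
        inside = PairedPath(nodes=(n[1], n[2], n[3]), cov=1.0, label=Label.L2_PLUS)
        outside = PairedPath(nodes=(n[0], n[2], n[3]), cov=1.0, label=Label.L2_PLUS)
        path = TranscriptPath(tuple(n), 1.0, Seed("edge", (n[0], n[1]), 5.0,
                                                  Label.L2_PLUS))
        update_graph(g, path, [inside, outside])
        assert inside.used and not outside.used

    def test_empty_graph_assembles_nothing(self):
        g = make_labeled_graph({}, {})
        assert assemble_locus(g, []) == []

    @pytest.mark.parametrize("seed_value", range(6))
    def test_termination_coverage_and_weight_conservation(self, seed_value):
        rng = random.Random(2000 + seed_value)
        g = _random_dag(rng, max_edges=12,
                        labels=(Label.L2_PLUS, Label.L2_MINUS, Label.L1))
        cap = len(g.edges) + len(g.nodes) + 1
        ledger = []
        out = assemble_locus(
            g, [], on_iteration=lambda p, b, a: ledger.append((p, b, a))
        )
        assert len(ledger) <= cap
        for path, before, after in ledger:
            n_real = len(path.nodes) - 1
            assert before - after == pytest.approx(path.f_min * n_real)
        assert all(e.covered for e in g.edges.values())
        covered = set()
        for t in out:
            covered.update(zip(t.nodes, t.nodes[1:]))
        assert covered >= set(g.edges)

    def test_every_transcript_contains_its_seed(self):
        rng = random.Random(31)
        for _ in range(10):
            g = _random_dag(rng)
            out = assemble_locus(g, [])
            for t in out:
                s = t.source_seed.nodes
                joined = False
                for i in range(len(t.nodes) - len(s) + 1):
                    if t.nodes[i : i + len(s)] == s:
                        joined = True
                assert joined

    def test_isolated_surviving_node_emitted_as_single_exon(self):
        n = chain_nodes(3)
        g = make_labeled_graph(
            {n[0]: 12.0, n[1]: 5.0, n[2]: 5.0},
            {(n[1], n[2]): (5.0, Label.L2_PLUS)},
        )
        out = assemble_locus(g, [])
        assert ((n[0],)) in [t.nodes for t in out]


class TestPathToTranscript:
    def test_adjacency_merges_junction_splits(self):
        a, b, c = (101, 150), (151, 200), (251, 300)
        g = make_labeled_graph(
            {a: 1.0, b: 1.0, c: 1.0},
            {
                (a, b): (1.0, Label.L2_PLUS, ADJACENCY),
                (b, c): (1.0, Label.L2_PLUS, JUNCTION),
            },
        )
        t = TranscriptPath((a, b, c), 1.0, Seed("edge", (a, b), 1.0, Label.L2_PLUS))
        assert path_to_transcript_exons(t, g) == [(101, 200), (251, 300)]

    def test_single_node_single_exon(self):
        a = (101, 400)
        g = make_labeled_graph({a: 1.0}, {})
        t = TranscriptPath((a,), 1.0, Seed("edge", (a,), 1.0, Label.L1))
        assert path_to_transcript_exons(t, g) == [(101, 400)]
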