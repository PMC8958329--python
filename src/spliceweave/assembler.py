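"""Transcript extraction by label-prioritized bottleneck dynamic programming.

The loop: pick the highest-priority unused seed (paired paths before bare
edges, cross-aligner agreement labels 2+ > 2- > 1, then largest weight),
extend it to the subgraph of everything upstream of its first node and
downstream of its last, run a bottleneck DP that prefers predecessors by
label class and then by the largest expression bound, trace back the
highest-expressed origin-to-destination path, subtract its bottleneck
f_min from the path's edges (relabeling zeroed edges to 1), and repeat
until every edge is covered and every seed consumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .labeled_graph import Label, LabeledSpliceGraph
from .paired_paths import NodePath, PairedPath
from .splice_graph import ADJACENCY, Interval

ORIGIN = "__origin__"
DEST = "__dest__"

_EPS = 1e-9


@dataclass(frozen=True)
class Seed:
    kind: str  # "paired_path" or "edge"
    nodes: NodePath
    cov: float
    label: Label
    source_path: PairedPath | None = None


@dataclass
class Subgraph:
    """Seed plus its backward and forward reachability cones, bracketed by
    synthetic origin/destination nodes via infinite-weight L1 connectors."""

    real_edges: set[tuple[Interval, Interval]]
    nodes: list[Interval]
    origin_targets: list[Interval]  # nodes without in-edges inside G_S
    dest_sources: list[Interval]  # nodes without out-edges inside G_S


@dataclass
class TranscriptPath:
    nodes: NodePath
    f_min: float
    source_seed: Seed


class _Adjacency:
    """Static out/in adjacency of the labeled graph (edge set never changes
    during assembly, only weights and labels do)."""

    def __init__(self, g: LabeledSpliceGraph):
        self.out: dict[Interval, list[tuple[Interval, Interval]]] = {}
        self.inc: dict[Interval, list[tuple[Interval, Interval]]] = {}
        for u, v in sorted(g.edges):
            self.out.setdefault(u, []).append((u, v))
            self.inc.setdefault(v, []).append((u, v))


def select_seed(
    g: LabeledSpliceGraph, pp: list[PairedPath], used_paths: set[int] | None = None
) -> Seed | None:
    """Pick the next seed by class priority, then largest weight.

    Class order: unused 2+ paired paths, unused 2- paired paths, uncovered
    2+ edges, uncovered 2- edges, then unused label-1 paired paths or
    uncovered label-1 edges together.  Ties break toward more nodes, then
    leftmost coordinate.  Returns None when every edge is covered and
    every paired path used.
    """
    path_pool = {
        Label.L2_PLUS: [],
        Label.L2_MINUS: [],
        Label.L1: [],
    }
    for p in pp:
        if not p.used:
            path_pool[p.label].append(
                Seed("paired_path", p.nodes, p.cov, p.label, source_path=p)
            )
    edge_pool = {Label.L2_PLUS: [], Label.L2_MINUS: [], Label.L1: []}
    for key, e in g.edges.items():
        if not e.covered:
            edge_pool[e.label].append(Seed("edge", key, e.weight, e.label))
    classes = [
        path_pool[Label.L2_PLUS],
        path_pool[Label.L2_MINUS],
        edge_pool[Label.L2_PLUS],
        edge_pool[Label.L2_MINUS],
        path_pool[Label.L1] + edge_pool[Label.L1],
    ]
    for pool in classes:
        if pool:
            return sorted(pool, key=lambda s: (-s.cov, -len(s.nodes), s.nodes))[0]
    return None


def extend_subgraph(
    g: LabeledSpliceGraph, seed: Seed, adj: _Adjacency | None = None
) -> Subgraph:
    """Seed plus all edges reachable from its last node and co-reachable to
    its first node; edges entering a cone node from outside are excluded."""
    adj = adj or _Adjacency(g)
    edges: set[tuple[Interval, Interval]] = set(
        zip(seed.nodes, seed.nodes[1:])
    )
    stack = [seed.nodes[-1]]
    seen = set()
    while stack:
        v = stack.pop()
        if v in seen:
            continue
        seen.add(v)
        for e in adj.out.get(v, ()):
            edges.add(e)
            stack.append(e[1])
    stack = [seed.nodes[0]]
    seen = set()
    while stack:
        v = stack.pop()
        if v in seen:
            continue
        seen.add(v)
        for e in adj.inc.get(v, ()):
            edges.add(e)
            stack.append(e[0])
    nodes = sorted({iv for e in edges for iv in e})
    has_in = {v for _, v in edges}
    has_out = {u for u, _ in edges}
    return Subgraph(
        real_edges=edges,
        nodes=nodes,
        origin_targets=[v for v in nodes if v not in has_in],
        dest_sources=[v for v in nodes if v not in has_out],
    )


def run_dp(gs: Subgraph, seed: Seed, g: LabeledSpliceGraph) -> TranscriptPath:
    """Bottleneck DP over the topologically ordered edges of the subgraph.

    Exp_i is an upper bound on the expression of the best path from the
    seed to edge i: Exp_i = min(weight(i), Exp_i') where the predecessor
    i' is chosen among already-assigned in-edges by label priority
    (2+ > 2- > 1) and, within a class, largest Exp.  Traceback starts at
    the destination (origin) connector of largest Exp and follows
    Pre (Suc) back to the seed.
    """
    topo = {ORIGIN: 0}
    for i, v in enumerate(gs.nodes, start=1):
        topo[v] = i
    topo[DEST] = len(gs.nodes) + 1

    # (src_topo, dst_topo, key, weight, label, is_connector)
    raw = [
        (topo[u], topo[v], (u, v), g.edges[(u, v)].weight, g.edges[(u, v)].label, False)
        for (u, v) in gs.real_edges
    ]
    raw += [
        (0, topo[v], (ORIGIN, v), math.inf, Label.L1, True)
        for v in gs.origin_targets
    ]
    raw += [
        (topo[u], topo[DEST], (u, DEST), math.inf, Label.L1, True)
        for u in gs.dest_sources
    ]
    raw.sort(key=lambda t: (t[0], t[1]))
    keys = [t[2] for t in raw]
    weights = [t[3] for t in raw]
    labels = [t[4] for t in raw]
    connector = [t[5] for t in raw]
    id_of = {k: i for i, k in enumerate(keys)}
    n_edges = len(raw)
    in_ids: dict[object, list[int]] = {}
    out_ids: dict[object, list[int]] = {}
    for i, (u, v) in enumerate(keys):
        out_ids.setdefault(u, []).append(i)
        in_ids.setdefault(v, []).append(i)

    seed_ids = [id_of[e] for e in zip(seed.nodes, seed.nodes[1:])]
    m, n = min(seed_ids), max(seed_ids)

    exp: dict[int, float] = {m: seed.cov, n: seed.cov}
    pre: dict[int, int] = {}
    suc: dict[int, int] = {}

    def best(cands: list[int]) -> int:
        return max(cands, key=lambda j: (labels[j], exp[j], -j))

    assigned_fwd = {n}
    for i in range(n + 1, n_edges):
        src = keys[i][0]
        cands = [j for j in in_ids.get(src, ()) if j in assigned_fwd]
        if not cands:
            continue
        j = best(cands)
        exp[i] = min(weights[i], exp[j])
        pre[i] = j
        assigned_fwd.add(i)

    assigned_bwd = {m}
    for i in range(m - 1, -1, -1):
        dst = keys[i][1]
        cands = [j for j in out_ids.get(dst, ()) if j in assigned_bwd]
        if not cands:
            continue
        j = best(cands)
        exp[i] = min(weights[i], exp[j])
        suc[i] = j
        assigned_bwd.add(i)

    dest_conn = [i for i in range(n_edges) if keys[i][1] == DEST and i in assigned_fwd]
    orig_conn = [i for i in range(n_edges) if keys[i][0] == ORIGIN and i in assigned_bwd]
    if not dest_conn or not orig_conn:
        raise RuntimeError("seed unreachable from origin/destination in subgraph")
    d = max(dest_conn, key=lambda i: (exp[i], -i))
    o = max(orig_conn, key=lambda i: (exp[i], -i))

    fwd_chain: list[int] = []
    cur = d
    while cur != n:
        fwd_chain.append(cur)
        cur = pre[cur]
    fwd_chain.reverse()  # edges from just-after-n up to the DEST connector
    bwd_chain: list[int] = []
    cur = o
    while cur != m:
        bwd_chain.append(cur)
        cur = suc[cur]  # edges from the ORIGIN connector down to just-before-m

    full = bwd_chain + seed_ids + fwd_chain
    # full[0] is the origin connector and full[-1] the destination connector,
    # so the dst endpoints of full[:-1] enumerate exactly the real nodes.
    path_nodes = tuple(keys[i][1] for i in full[:-1])
    f_min = min(weights[i] for i in full if not connector[i])
    return TranscriptPath(nodes=path_nodes, f_min=f_min, source_seed=seed)


def update_graph(
    g: LabeledSpliceGraph, path: TranscriptPath, pp: list[PairedPath]
) -> None:
    """Subtract f_min along the path, downgrade zeroed edges to label 1,
    mark path edges covered and contained paired paths used."""
    for key in zip(path.nodes, path.nodes[1:]):
        e = g.edges[key]
        e.weight = max(0.0, e.weight - path.f_min)
        if e.weight <= _EPS:
            e.weight = 0.0
            e.label = Label.L1
        e.covered = True
    for p in pp:
        if not p.used and _contains_subpath(path.nodes, p.nodes):
            p.used = True


def _contains_subpath(path: NodePath, sub: NodePath) -> bool:
    ls, lp = len(sub), len(path)
    return any(path[i : i + ls] == sub for i in range(lp - ls + 1))


def assemble_locus(
    g: LabeledSpliceGraph,
    pp: list[PairedPath],
    locus_id: str = "locus",
    on_iteration=None,
) -> list[TranscriptPath]:
    """Run the seed/extend/DP/update loop until all edges are covered and
    all paired paths used; emit isolated surviving nodes as single-exon
    transcripts.  Exceeding the iteration cap |E|+|PP|+|V| is an error.

    ``on_iteration(path, total_weight_before, total_weight_after)`` is
    invoked after each update, mainly for instrumentation.
    """
    adj = _Adjacency(g)
    cap = len(g.edges) + len(pp) + len(g.nodes) + 1
    out: list[TranscriptPath] = []
    seen: set[NodePath] = set()
    iterations = 0
    while True:
        seed = select_seed(g, pp)
        if seed is None:
            break
        iterations += 1
        if iterations > cap:
            raise RuntimeError(
                f"{locus_id}: assembly did not converge within {cap} iterations"
            )
        gs = extend_subgraph(g, seed, adj)
        path = run_dp(gs, seed, g)
        before = sum(e.weight for e in g.edges.values())
        update_graph(g, path, pp)
        if on_iteration is not None:
            on_iteration(path, before, sum(e.weight for e in g.edges.values()))
        if seed.source_path is not None:
            seed.source_path.used = True
        if path.nodes not in seen:
            seen.add(path.nodes)
            out.append(path)
    linked = {iv for key in g.edges for iv in key}
    for iv in g.node_order:
        if iv not in linked and (iv,) not in seen:
            seen.add((iv,))
            out.append(
                TranscriptPath(
                    nodes=(iv,),
                    f_min=g.nodes[iv],
                    source_seed=Seed("edge", (iv,), g.nodes[iv], Label.L1),
                )
            )
    return out


def path_to_transcript_exons(
    path: TranscriptPath, g: LabeledSpliceGraph
) -> list[Interval]:
    """Merge consecutive nodes joined by adjacency edges into exons;
    junction edges become introns."""
    exons: list[list[int]] = []
    for i, iv in enumerate(path.nodes):
        if i > 0:
            key = (path.nodes[i - 1], iv)
            if g.edges[key].kind == ADJACENCY:
                exons[-1][1] = iv[1]
                continue
        exons.append([iv[0], iv[1]])
    return [(s, e) for s, e in exons]
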