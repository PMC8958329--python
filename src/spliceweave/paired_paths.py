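"""Paired paths: node paths induced by mate pairs on the labeled graph.

A mate pair whose two per-mate paths share a terminal sub-path containing
at least one edge, with a union of at least three nodes (k + q - s >= 3),
yields a paired path.  Paired paths are collected per aligner, merged and
labeled exactly like edges, and serve as the preferred seeds for
transcript extraction.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

from .alignment_io import AlignedRead
from .labeled_graph import Label, LabeledSpliceGraph, label_edge
from .splice_graph import Interval

NodePath = tuple[Interval, ...]


@dataclass
class PairedPath:
    nodes: NodePath
    cov: float
    label: Label = Label.L2_PLUS
    read_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    used: bool = False


def map_read_to_path(
    read: AlignedRead, g: LabeledSpliceGraph
) -> NodePath | None:
    """Project one mate's blocks onto the graph's node path, or None.

    The projection exists iff every junction of the read is an edge of the
    (filtered, merged) graph, consecutive within-block segments are linked
    by adjacency edges, and the blocks cover each internal node end-to-end.
    """
    order = g.node_order
    starts = [iv[0] for iv in order]

    def node_at(pos: int) -> Interval | None:
        i = bisect_right(starts, pos) - 1
        if i >= 0 and order[i][0] <= pos <= order[i][1]:
            return order[i]
        return None

    path: list[Interval] = []
    n_blocks = len(read.blocks)
    for bi, (bs, be) in enumerate(read.blocks):
        node = node_at(bs)
        if node is None:
            return None
        if bi > 0:
            if node[0] != bs:
                return None  # acceptor must open a segment
            if (path[-1], node) not in g.edges:
                return None  # junction was filtered from the graph
        path.append(node)
        # walk contiguous segments inside the block
        while node[1] < be:
            nxt = node_at(node[1] + 1)
            if nxt is None or nxt[0] != node[1] + 1:
                return None
            if (node, nxt) not in g.edges:
                return None  # adjacency filtered out
            path.append(nxt)
            node = nxt
        if bi < n_blocks - 1 and node[1] != be:
            return None  # donor must close a segment
    return tuple(path)


def join_mate_paths(p1: NodePath, p2: NodePath) -> NodePath | None:
    """Join two mate paths through their shared terminal sub-path.

    Returns the union path of k + q - s nodes when the maximal shared
    terminal sub-path has s >= 2 nodes (>= 1 edge) and k + q - s >= 3;
    otherwise None.  Symmetric in its arguments.
    """
    if not p1 or not p2:
        return None
    a, b = (p1, p2) if (p1[0], -len(p1)) <= (p2[0], -len(p2)) else (p2, p1)
    # containment: b a contiguous sub-path of a
    la, lb = len(a), len(b)
    for off in range(la - lb + 1):
        if a[off : off + lb] == b:
            s = lb
            if s >= 2 and la >= 3:
                return a
            return None
    for s in range(min(la, lb), 0, -1):
        if a[la - s :] == b[:s]:
            if s >= 2 and la + lb - s >= 3:
                return a + b[s:]
            return None
    return None


def collect_paired_paths(
    reads: list[AlignedRead], g: LabeledSpliceGraph
) -> list[PairedPath]:
    """Build the aligner's paired-path set PP_i with coverages.

    Fragments are paired by query name; a fragment whose mates map with
    different NH contributes 1/max(nh1, nh2).  Identical node sequences
    are deduplicated, summing coverage and pooling fragment ids.
    """
    by_name: dict[str, dict[int, list[AlignedRead]]] = {}
    for r in reads:
        by_name.setdefault(r.read_id, {}).setdefault(r.mate, []).append(r)
    paths: dict[NodePath, PairedPath] = {}
    for name in by_name:
        mates = by_name[name]
        if 1 not in mates or 2 not in mates:
            continue
        for r1 in mates[1]:
            p1 = map_read_to_path(r1, g)
            if p1 is None:
                continue
            for r2 in mates[2]:
                p2 = map_read_to_path(r2, g)
                if p2 is None:
                    continue
                joined = join_mate_paths(p1, p2)
                if joined is None:
                    continue
                w = 1.0 / max(r1.nh, r2.nh)
                pp = paths.get(joined)
                if pp is None:
                    paths[joined] = PairedPath(
                        nodes=joined, cov=w, read_sets={"_frags": frozenset([name])}
                    )
                else:
                    pp.cov += w
                    pp.read_sets["_frags"] = pp.read_sets["_frags"] | {name}
    return sorted(paths.values(), key=lambda p: p.nodes)


def label_paired_paths(
    per_aligner: dict[str, list[PairedPath]]
) -> list[PairedPath]:
    """Union per-aligner paired-path sets into PP_L, labeled like edges.

    Coverage is the mean over the aligners in which the path appears;
    the label follows the edge rule with fragment-id sets in place of
    read-id sets.
    """
    aligners = list(per_aligner)
    by_nodes: dict[NodePath, dict[str, PairedPath]] = {}
    for aid in aligners:
        for pp in per_aligner[aid]:
            by_nodes.setdefault(pp.nodes, {})[aid] = pp
    out: list[PairedPath] = []
    for nodes in sorted(by_nodes):
        parts = by_nodes[nodes]
        presence = [aid in parts for aid in aligners]
        frag_sets = [
            parts[aid].read_sets["_frags"] if aid in parts else None
            for aid in aligners
        ]
        label = label_edge(presence, frag_sets)
        cov = sum(p.cov for p in parts.values()) / len(parts)
        out.append(
            PairedPath(
                nodes=nodes,
                cov=cov,
                label=label,
                read_sets={
                    aid: parts[aid].read_sets["_frags"] for aid in parts
                },
            )
        )
    return out
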