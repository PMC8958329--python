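"""Per-aligner splice graphs: exon segmentation, weighting, and filtering.

A locus is segmented into partial exons on a boundary set shared across
all aligners (union coverage cut at every aligner's splice sites), so the
per-aligner graphs live in one node coordinate space and merging is exact
interval matching.  Nodes are weighted by average per-base coverage,
junction edges by spliced-read support, and adjacency edges (between
genomically contiguous segments) by reads whose single block spans the
shared boundary.  Five weight-based criteria then prune likely artifacts.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field, replace

import numpy as np

from .alignment_io import Locus

Interval = tuple[int, int]

JUNCTION = "junction"
ADJACENCY = "adjacency"


@dataclass
class Edge:
    weight: float
    reads: set[str] = field(default_factory=set)
    kind: str = JUNCTION


@dataclass
class SpliceGraph:
    """DAG of exon segments for one aligner at one locus.

    Edges are keyed by (source interval, target interval) and always point
    coordinate-forward, so acyclicity is structural.
    """

    aligner_id: str
    chrom: str
    strand: str
    nodes: dict[Interval, float] = field(default_factory=dict)
    edges: dict[tuple[Interval, Interval], Edge] = field(default_factory=dict)

    def out_edges(self, iv: Interval) -> list[tuple[Interval, Interval]]:
        return [k for k in self.edges if k[0] == iv]

    def in_edges(self, iv: Interval) -> list[tuple[Interval, Interval]]:
        return [k for k in self.edges if k[1] == iv]


@dataclass(frozen=True)
class FilterParams:
    """Pruning thresholds (defaults are the method's published values)."""

    min_junction_weight: float = 1.0
    branch_ratio: float = 0.1
    cross_ratio: float = 0.03
    mean_ratio: float = 0.02
    min_single_exon_cov: float = 10.0


def derive_boundaries(locus: Locus) -> list[Interval]:
    """Partition the locus's cross-aligner union coverage into segments.

    Cut points are the union over ALL aligners of {donor+1, acceptor}
    positions plus the starts/stops of covered runs.  The identical
    segmentation is used for every aligner's graph.
    """
    lo, hi = locus.span
    covered = np.zeros(hi - lo + 2, dtype=bool)
    for reads in locus.reads.values():
        for r in reads:
            for bs, be in r.blocks:
                covered[bs - lo : be - lo + 1] = True
    cuts: set[int] = set()
    for support in locus.junction_support.values():
        for j in support:
            cuts.add(j.donor + 1)
            cuts.add(j.acceptor)
    segments: list[Interval] = []
    padded = np.concatenate(([False], covered, [False]))
    diff = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(diff == 1) + lo
    run_ends = np.flatnonzero(diff == -1) + lo - 1
    for rs, re in zip(run_starts, run_ends):
        _cut_run(int(rs), int(re), cuts, segments)
    return segments


def _cut_run(rs: int, re: int, cuts: set[int], out: list[Interval]) -> None:
    starts = [rs] + sorted(c for c in cuts if rs < c <= re)
    for i, s in enumerate(starts):
        e = starts[i + 1] - 1 if i + 1 < len(starts) else re
        out.append((s, e))


def build_graph(
    locus: Locus, aligner_id: str, boundaries: list[Interval]
) -> SpliceGraph:
    """Build one aligner's weighted splice graph on the shared segmentation.

    Node weight is the average per-base coverage from this aligner's reads
    (each mate counted, deletions covered, introns not); junction edges
    carry summed 1/NH support; adjacency edges connect contiguous segments
    when at least one read block spans the shared boundary.
    """
    g = SpliceGraph(aligner_id=aligner_id, chrom=locus.chrom, strand=locus.strand)
    reads = locus.reads.get(aligner_id, [])
    support = locus.junction_support.get(aligner_id, {})
    if not reads and not support:
        return g
    lo, hi = locus.span
    cov = np.zeros(hi - lo + 2, dtype=float)
    for r in reads:
        for bs, be in r.blocks:
            cov[bs - lo : be - lo + 1] += r.contribution

    by_end = {e: (s, e) for s, e in boundaries}
    by_start = {s: (s, e) for s, e in boundaries}
    touched: set[Interval] = set()
    for j in support:
        if j.donor in by_end:
            touched.add(by_end[j.donor])
        if j.acceptor in by_start:
            touched.add(by_start[j.acceptor])
    for s, e in boundaries:
        w = float(cov[s - lo : e - lo + 1].mean())
        if w > 0 or (s, e) in touched:
            g.nodes[(s, e)] = w

    for j, (w, ids) in support.items():
        u, v = by_end.get(j.donor), by_start.get(j.acceptor)
        if u is None or v is None:
            continue
        g.nodes.setdefault(u, float(cov[u[0] - lo : u[1] - lo + 1].mean()))
        g.nodes.setdefault(v, float(cov[v[0] - lo : v[1] - lo + 1].mean()))
        g.edges[(u, v)] = Edge(weight=w, reads=set(ids), kind=JUNCTION)

    # adjacency edges between contiguous segments spanned by a read block
    boundary_pos = {
        u[1]: (u, v)
        for u in boundaries
        for v in (by_start.get(u[1] + 1),)
        if v is not None
    }
    sorted_bounds = sorted(boundary_pos)
    for r in reads:
        for bs, be in r.blocks:
            i = bisect_left(sorted_bounds, bs)
            while i < len(sorted_bounds) and sorted_bounds[i] < be:
                u, v = boundary_pos[sorted_bounds[i]]
                i += 1
                if u in g.nodes and v in g.nodes:
                    edge = g.edges.setdefault((u, v), Edge(weight=0.0, kind=ADJACENCY))
                    if r.mate_id not in edge.reads:
                        edge.weight += r.contribution
                        edge.reads.add(r.mate_id)
    return g


def filter_graph(g: SpliceGraph, params: FilterParams = FilterParams()) -> SpliceGraph:
    """Apply the five pruning criteria, one pass each, in order.

    1. drop edges with weight < 1 (strictly below);
    2. at nodes with >= 2 out-edges (resp. in-edges), drop any such edge
       whose weight is < 10% of the node's total out- (in-) weight;
    3. drop out-edges lighter than 3% of the node's total in-weight, and
       symmetrically in-edges lighter than 3% of the total out-weight;
    4. drop edges lighter than 2% of the graph's mean edge weight (mean
       taken as the graph stands entering this criterion);
    5. drop isolated nodes (no in- and no out-edges) with weight < 10.

    Weights are never increased and no edge is ever added.
    """
    out = SpliceGraph(
        aligner_id=g.aligner_id,
        chrom=g.chrom,
        strand=g.strand,
        nodes=dict(g.nodes),
        edges={k: replace(e, reads=set(e.reads)) for k, e in g.edges.items()},
    )
    # 1: absolute junction support
    for k in [k for k, e in out.edges.items() if e.weight < params.min_junction_weight]:
        del out.edges[k]

    # 2: branch ratio at multi-edge nodes
    doomed: set[tuple[Interval, Interval]] = set()
    for iv in out.nodes:
        for keys in (out.out_edges(iv), out.in_edges(iv)):
            if len(keys) < 2:
                continue
            total = sum(out.edges[k].weight for k in keys)
            for k in keys:
                if out.edges[k].weight < params.branch_ratio * total:
                    doomed.add(k)
    for k in doomed:
        del out.edges[k]

    # 3: cross-directional ratio
    doomed = set()
    for iv in out.nodes:
        total_in = sum(out.edges[k].weight for k in out.in_edges(iv))
        total_out = sum(out.edges[k].weight for k in out.out_edges(iv))
        for k in out.out_edges(iv):
            if total_in and out.edges[k].weight < params.cross_ratio * total_in:
                doomed.add(k)
        for k in out.in_edges(iv):
            if total_out and out.edges[k].weight < params.cross_ratio * total_out:
                doomed.add(k)
    for k in doomed:
        del out.edges[k]

    # 4: fraction of the mean edge weight
    if out.edges:
        mean_w = sum(e.weight for e in out.edges.values()) / len(out.edges)
        for k in [
            k for k, e in out.edges.items() if e.weight < params.mean_ratio * mean_w
        ]:
            del out.edges[k]

    # 5: weak isolated nodes
    linked = {iv for k in out.edges for iv in k}
    for iv in [
        iv
        for iv, w in out.nodes.items()
        if iv not in linked and w < params.min_single_exon_cov
    ]:
        del out.nodes[iv]

    for iv in [
        iv for iv, w in out.nodes.items() if w == 0 and iv not in linked
    ]:
        del out.nodes[iv]
    return out
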