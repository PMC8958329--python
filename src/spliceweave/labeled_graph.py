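"""Merge per-aligner splice graphs into one labeled splice graph.

Each edge of the merged graph carries a label recording cross-aligner
agreement: ``L1`` if it is absent from at least one aligner's graph,
``L2_PLUS`` if all aligners report it with identical supporting read
sets, ``L2_MINUS`` if all report it but the read sets differ.  Weights
are arithmetic means over the graphs in which the element appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

from .splice_graph import Edge, Interval, SpliceGraph


class Label(IntEnum):
    """Cross-aligner agreement label; larger value = higher priority."""

    L1 = 1
    L2_MINUS = 2
    L2_PLUS = 3


@dataclass
class LabeledEdge:
    weight: float
    label: Label
    kind: str
    read_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    covered: bool = False


@dataclass
class LabeledSpliceGraph:
    chrom: str
    strand: str
    n_aligners: int
    nodes: dict[Interval, float] = field(default_factory=dict)
    edges: dict[tuple[Interval, Interval], LabeledEdge] = field(default_factory=dict)

    @property
    def node_order(self) -> list[Interval]:
        return sorted(self.nodes)

    def out_edges(self, iv: Interval) -> list[tuple[Interval, Interval]]:
        return [k for k in self.edges if k[0] == iv]

    def in_edges(self, iv: Interval) -> list[tuple[Interval, Interval]]:
        return [k for k in self.edges if k[1] == iv]


def label_edge(
    presence: Sequence[bool], read_sets: Sequence[frozenset[str] | None]
) -> Label:
    """Label from per-aligner presence flags and supporting read sets.

    Absent from any aligner -> L1; present everywhere with all read sets
    equal -> L2_PLUS; present everywhere otherwise -> L2_MINUS.
    """
    if len(presence) == 0:
        raise ValueError("need at least one aligner")
    if not all(presence):
        return Label.L1
    sets = [s for s in read_sets if s is not None]
    first = sets[0]
    return Label.L2_PLUS if all(s == first for s in sets[1:]) else Label.L2_MINUS


def _check_node_compatibility(graphs: Sequence[SpliceGraph]) -> None:
    intervals = sorted({iv for g in graphs for iv in g.nodes})
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 <= e1:
            raise ValueError(
                f"partially overlapping node intervals ({s1},{e1}) vs ({s2},{e2}): "
                "graphs were not built on a shared boundary set"
            )


def merge_graphs(graphs: Sequence[SpliceGraph]) -> LabeledSpliceGraph:
    """Union nodes and edges across aligners, averaging weights and labeling
    every edge by :func:`label_edge`."""
    if not graphs:
        raise ValueError("need at least one splice graph")
    _check_node_compatibility(graphs)
    n = len(graphs)
    merged = LabeledSpliceGraph(
        chrom=graphs[0].chrom, strand=graphs[0].strand, n_aligners=n
    )
    for iv in sorted({iv for g in graphs for iv in g.nodes}):
        ws = [g.nodes[iv] for g in graphs if iv in g.nodes]
        merged.nodes[iv] = sum(ws) / len(ws)
    for key in sorted({k for g in graphs for k in g.edges}):
        present = [key in g.edges for g in graphs]
        parts: list[Edge] = [g.edges[key] for g in graphs if key in g.edges]
        read_sets = {
            g.aligner_id: frozenset(g.edges[key].reads)
            for g in graphs
            if key in g.edges
        }
        label = label_edge(
            present,
            [
                frozenset(g.edges[key].reads) if key in g.edges else None
                for g in graphs
            ],
        )
        merged.edges[key] = LabeledEdge(
            weight=sum(e.weight for e in parts) / len(parts),
            label=label,
            kind=parts[0].kind,
            read_sets=read_sets,
        )
    return merged
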