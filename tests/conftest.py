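"""Shared builders: in-memory reads, tiny SAM files, and hand-made graphs."""

from __future__ import annotations

import pysam
import pytest

from spliceweave.alignment_io import AlignedRead
from spliceweave.labeled_graph import Label, LabeledEdge, LabeledSpliceGraph
from spliceweave.splice_graph import ADJACENCY, JUNCTION, Edge, SpliceGraph


def make_read(
    read_id="r1",
    mate=1,
    aligner_id="A",
    chrom="chr1",
    blocks=((101, 150),),
    nh=1,
    strand_hint=None,
):
    return AlignedRead(
        read_id=read_id,
        mate=mate,
        aligner_id=aligner_id,
        chrom=chrom,
        strand_hint=strand_hint,
        blocks=tuple(tuple(b) for b in blocks),
        nh=nh,
    )


def make_splice_graph(nodes, edges, aligner_id="A", chrom="chr1", strand="+"):
    """nodes: {interval: weight}; edges: {(u, v): (weight, reads, kind)}."""
    g = SpliceGraph(aligner_id=aligner_id, chrom=chrom, strand=strand)
    g.nodes = dict(nodes)
    for key, spec in edges.items():
        weight, reads, kind = spec
        g.edges[key] = Edge(weight=weight, reads=set(reads), kind=kind)
    return g


def make_labeled_graph(nodes, edges, chrom="chr1", strand="+", n_aligners=2):
    """nodes: {interval: weight}; edges: {(u,v): (weight, label)} or
    {(u,v): (weight, label, kind)}."""
    g = LabeledSpliceGraph(
        chrom=chrom, strand=strand, n_aligners=n_aligners
    )
    g.nodes = dict(nodes)
    for key, spec in edges.items():
        if len(spec) == 2:
            weight, label = spec
            kind = JUNCTION
        else:
            weight, label, kind = spec
        g.edges[key] = LabeledEdge(weight=weight, label=label, kind=kind)
    return g


def chain_nodes(n, start=1000, length=100, gap=200):
    """n non-adjacent interval nodes in coordinate order."""
    out = []
    pos = start
    for _ in range(n):
        out.append((pos, pos + length - 1))
        pos += length + gap
    return out


@pytest.fixture
def sam_factory(tmp_path):
    """Write a small coordinate-sorted SAM from record tuples:
    (qname, flag, pos, cigar) with optional dict of extras (nh, xs)."""

    counter = [0]

    def write(records, chrom="chr1", chrom_len=1_000_000, sort_order="coordinate"):
        counter[0] += 1
        path = tmp_path / f"fixture{counter[0]}.sam"
        header = pysam.AlignmentHeader.from_dict(
            {
                "HD": {"VN": "1.6", "SO": sort_order},
                "SQ": [{"SN": chrom, "LN": chrom_len}],
            }
        )
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for rec in records:
                qname, flag, pos, cigar = rec[:4]
                extras = rec[4] if len(rec) > 4 else {}
                a = pysam.AlignedSegment(header)
                a.query_name = qname
                a.flag = flag
                a.reference_name = chrom
                a.reference_start = pos - 1
                a.mapping_quality = 60
                a.cigarstring = cigar
                qlen = a.infer_query_length() or 0
                a.query_sequence = "N" * qlen
                tags = [("NH", extras.get("nh", 1))]
                if "xs" in extras:
                    tags.append(("XS", extras["xs"]))
                a.set_tags(tags)
                out.write(a)
        return str(path)

    return write
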