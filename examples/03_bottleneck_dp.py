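"""The label-prioritized bottleneck DP on a hand-built diamond graph.

Two origin-to-destination routes share the seed edge. With uniform
labels the DP takes the route with the larger bottleneck (minimum edge
weight); downgrading that route's closing edge to label 1 flips the
choice — cross-aligner reliability outranks expression.
"""

from spliceweave.assembler import Seed, extend_subgraph, run_dp
from spliceweave.labeled_graph import Label, LabeledEdge, LabeledSpliceGraph

nodes = [(i * 300 + 1, i * 300 + 100) for i in range(5)]
n1, n2, n3, n4, n5 = nodes


def diamond(label_35, label_45):
    g = LabeledSpliceGraph(chrom="chr1", strand="+", n_aligners=2)
    g.nodes = {iv: 10.0 for iv in nodes}
    for key, w, lab in [
        ((n1, n2), 10.0, Label.L2_PLUS),
        ((n2, n3), 8.0, Label.L2_PLUS),
        ((n2, n4), 5.0, Label.L2_PLUS),
        ((n3, n5), 6.0, label_35),
        ((n4, n5), 9.0, label_45),
    ]:
        g.edges[key] = LabeledEdge(weight=w, label=lab, kind="junction")
    return g


def show(tag, g):
    seed = Seed("edge", (n1, n2), 10.0, Label.L2_PLUS)
    path = run_dp(extend_subgraph(g, seed), seed, g)
    route = " -> ".join(str(nodes.index(iv) + 1) for iv in path.nodes)
    print(f"{tag}: path {route}, bottleneck f_min = {path.f_min}")


show("uniform 2+ labels      ", diamond(Label.L2_PLUS, Label.L2_PLUS))
show("upper route closes as 1", diamond(Label.L1, Label.L2_PLUS))
# first line: min(10,8,6)=6 beats min(10,5,9)=5, so the upper route wins;
# second line: the label-1 edge is avoided despite its larger bottleneck
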