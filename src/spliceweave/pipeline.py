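"""End-to-end assembly: SAM/BAM inputs from several aligners to transcripts.

This is the library face of the tool: :func:`assemble_files` runs the
whole method (locus clustering, per-aligner graph construction and
filtering, merging with labels, paired-path extraction, and the
label-prioritized bottleneck DP) and returns :class:`~spliceweave.gtf.Transcript`
objects ready for GTF emission.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from .alignment_io import Locus, cluster_loci, read_alignments
from .assembler import assemble_locus, path_to_transcript_exons
from .gtf import Transcript
from .labeled_graph import LabeledSpliceGraph, merge_graphs
from .paired_paths import collect_paired_paths, label_paired_paths
from .splice_graph import FilterParams, build_graph, derive_boundaries, filter_graph

logger = logging.getLogger(__name__)


@dataclass
class AssemblyParams:
    filters: FilterParams = field(default_factory=FilterParams)
    min_transcript_length: int = 200


def assemble_one_locus(
    locus: Locus,
    aligner_ids: list[str],
    params: AssemblyParams,
):
    """Run graph construction through path extraction for one locus.

    Returns the merged labeled graph and the extracted transcript paths,
    before exon merging and length filtering.
    """
    boundaries = derive_boundaries(locus)
    graphs = [
        filter_graph(build_graph(locus, aid, boundaries), params.filters)
        for aid in aligner_ids
    ]
    merged = merge_graphs(graphs)
    if not merged.nodes:
        return merged, []
    per_aligner = {
        aid: collect_paired_paths(locus.reads.get(aid, []), merged)
        for aid in aligner_ids
    }
    pp = label_paired_paths(per_aligner)
    locus_id = f"{locus.chrom}:{locus.span[0]}-{locus.span[1]}"
    paths = assemble_locus(merged, pp, locus_id=locus_id)
    return merged, paths


def assemble_files(
    paths: list[str],
    aligner_ids: list[str] | None = None,
    params: AssemblyParams | None = None,
) -> list[Transcript]:
    """Assemble transcripts from one coordinate-sorted SAM/BAM per aligner."""
    params = params or AssemblyParams()
    if aligner_ids is None:
        aligner_ids = [f"bam{i+1}" for i in range(len(paths))]
    if len(aligner_ids) != len(paths):
        raise ValueError("one aligner id per input file required")
    reads_by_aligner = {
        aid: list(read_alignments(path, aid))
        for path, aid in zip(paths, aligner_ids)
    }
    n_records = sum(len(v) for v in reads_by_aligner.values())
    if n_records == 0:
        raise ValueError("no parsable alignment records in any input")
    loci = cluster_loci(reads_by_aligner)
    loci.sort(key=lambda lo: (lo.chrom, lo.span, lo.strand))
    logger.info("clustered %d records into %d loci", n_records, len(loci))

    transcripts: list[Transcript] = []
    for k, locus in enumerate(loci, start=1):
        merged, extracted = assemble_one_locus(locus, aligner_ids, params)
        kept = []
        for path in extracted:
            exons = tuple(path_to_transcript_exons(path, merged))
            length = sum(e - s + 1 for s, e in exons)
            if length < params.min_transcript_length:
                continue
            kept.append((exons, path.f_min))
        kept.sort(key=lambda t: (t[0][0], t[0]))
        for m, (exons, cov) in enumerate(kept, start=1):
            strand = locus.strand
            transcripts.append(
                Transcript(
                    chrom=locus.chrom,
                    strand=strand,
                    exons=exons,
                    gene_id=f"locus.{k}",
                    transcript_id=f"locus.{k}.{m}",
                    cov=cov,
                )
            )
        logger.info(
            "locus %d (%s:%d-%d): %d transcripts",
            k,
            locus.chrom,
            locus.span[0],
            locus.span[1],
            len(kept),
        )
    return transcripts


def dump_graph_dot(g: LabeledSpliceGraph, path: str) -> None:
    """Write the labeled graph in DOT, edges colored by label."""
    from .labeled_graph import Label

    colors = {Label.L2_PLUS: "green", Label.L2_MINUS: "orange", Label.L1: "gray"}
    with open(path, "w") as fh:
        fh.write("digraph locus {\n")
        for iv, w in sorted(g.nodes.items()):
            fh.write(f'  "{iv[0]}-{iv[1]}" [label="{iv[0]}-{iv[1]}\\n{w:.1f}"];\n')
        for (u, v), e in sorted(g.edges.items()):
            fh.write(
                f'  "{u[0]}-{u[1]}" -> "{v[0]}-{v[1]}" '
                f'[label="{e.weight:.1f}", color={colors[e.label]}];\n'
            )
        fh.write("}\n")
    logger.debug("wrote %s", os.path.abspath(path))
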