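"""Transcript models and GTF emission."""

from __future__ import annotations

from dataclasses import dataclass

from .splice_graph import Interval

SOURCE = "spliceweave"


@dataclass(frozen=True)
class Transcript:
    chrom: str
    strand: str  # '+', '-' or '.'
    exons: tuple[Interval, ...]  # sorted, 1-based inclusive, non-adjacent
    gene_id: str
    transcript_id: str
    cov: float

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


def write_gtf(transcripts: list[Transcript], path: str) -> None:
    """Write transcript and exon records, 1-based inclusive, deterministically
    ordered by (chrom, start, transcript_id)."""
    ordered = sorted(transcripts, key=lambda t: (t.chrom, t.span[0], t.transcript_id))
    with open(path, "w") as fh:
        fh.write(f"# {SOURCE} assembled transcripts\n")
        for t in ordered:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'cov "{t.cov:.4f}";'
            )
            s, e = t.span
            fh.write(
                f"{t.chrom}\t{SOURCE}\ttranscript\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for i, (es, ee) in enumerate(t.exons, start=1):
                fh.write(
                    f"{t.chrom}\t{SOURCE}\texon\t{es}\t{ee}\t.\t{t.strand}\t.\t"
                    f'{attrs} exon_number "{i}";\n'
                )


def read_exon_chains(path: str) -> dict[str, tuple[str, str, tuple[Interval, ...]]]:
    """Parse a GTF into transcript_id -> (chrom, strand, sorted exon chain)."""
    import gffutils

    with open(path) as fh:
        has_records = any(
            line.strip() and not line.startswith("#") for line in fh
        )
    if not has_records:
        return {}
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    chains: dict[str, tuple[str, str, list[Interval]]] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes["transcript_id"][0]
        chrom, strand = feat.seqid, feat.strand
        chains.setdefault(tid, (chrom, strand, []))[2].append((feat.start, feat.end))
    return {
        tid: (chrom, strand, tuple(sorted(exons)))
        for tid, (chrom, strand, exons) in chains.items()
    }
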