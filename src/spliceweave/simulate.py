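"""Synthetic truth sets, fragment simulation, and aligner emulation.

The generator builds toy multi-isoform gene loci, samples paired-end
fragments proportional to expression, and writes one coordinate-sorted
SAM per emulated aligner.  Aligner profiles control per-aligner junction
dropout (a junction one mapper systematically misses), read-set jitter on
shared junctions (renamed reads, forcing 2- labels after merging), and
multi-mapping (fragments duplicated to a decoy region with NH=2).

Genome sequence content is never needed downstream, so SEQ fields are
written as N-runs of the correct length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .gtf import Transcript, write_gtf
from .splice_graph import Interval


@dataclass(frozen=True)
class TruthTranscript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    expression: float

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """(donor, acceptor) pairs, i.e. exonic flanks of each intron."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass(frozen=True)
class TruthSet:
    genome: dict[str, int]  # sequence name -> length
    transcripts: tuple[TruthTranscript, ...]
    rng_seed: int


@dataclass(frozen=True)
class AlignerProfile:
    aligner_id: str
    junction_dropout: frozenset[tuple[int, int]] = frozenset()
    readset_jitter: float = 0.0  # fraction of junction fragments renamed
    multimap_frac: float = 0.0  # fraction of fragments duplicated with NH=2


@dataclass(frozen=True)
class Fragment:
    frag_id: str
    chrom: str
    strand: str
    mate1_blocks: tuple[Interval, ...]
    mate2_blocks: tuple[Interval, ...]

    def junctions(self) -> set[tuple[int, int]]:
        out = set()
        for blocks in (self.mate1_blocks, self.mate2_blocks):
            for i in range(len(blocks) - 1):
                out.add((blocks[i][1], blocks[i + 1][0]))
        return out


def _variant_chains(
    backbone: list[Interval],
    slot: int,
    n_isoforms: int,
    alt_donor: bool,
    alt_exon: Interval,
    donor_ext: int,
) -> list[tuple[Interval, ...]]:
    """Isoform exon chains around a single alternative region.

    Variant menu at the slot exon X (keeping every maximal graph path a
    true chain): the plain backbone; either a skipped exon or an extended
    5' donor (X lengthened by ``donor_ext``); an alternative exon Y inside
    the downstream intron; and X (short form) followed by Y.
    """
    x = backbone[slot]
    chains = [tuple(backbone)]
    if n_isoforms >= 2:
        if alt_donor:
            longer = backbone.copy()
            longer[slot] = (x[0], x[1] + donor_ext)
            chains.append(tuple(longer))
        else:
            chains.append(tuple(backbone[:slot] + backbone[slot + 1 :]))
    if n_isoforms >= 3:
        swapped = backbone.copy()
        swapped[slot] = alt_exon
        chains.append(tuple(swapped))
    if n_isoforms >= 4:
        tandem = backbone[: slot + 1] + [alt_exon] + backbone[slot + 1 :]
        chains.append(tuple(tandem))
    return chains[:n_isoforms]


def make_truth(
    n_loci: int,
    isoforms_per_locus: int,
    rng_seed: int,
    chrom: str = "chr1",
) -> TruthSet:
    """Reproducible multi-isoform loci sharing flanking exons.

    Expression is drawn as a log-uniform per-locus total (creating
    low/mid/high loci) split among isoforms with shares in [0.7, 1] before
    normalisation, so no isoform falls below ~19% of its locus - every
    real junction then clears the relative-weight filters at ample depth.
    """
    if n_loci < 1 or not 1 <= isoforms_per_locus <= 4:
        raise ValueError("n_loci >= 1 and 1 <= isoforms_per_locus <= 4 required")
    rng = np.random.default_rng(rng_seed)
    transcripts: list[TruthTranscript] = []
    cursor = 10_000
    for li in range(1, n_loci + 1):
        # >= 2 exons flank the alternative region on each side so event
        # junctions sit deeper than one fragment length from both transcript
        # ends: both mates' windows can span them, keeping branch shares
        # proportional to expression.
        n_exons = int(rng.integers(5, 8))
        slot = int(rng.integers(2, n_exons - 2))
        backbone: list[Interval] = []
        pos = cursor
        alt_exon: Interval = (0, 0)
        for ei in range(n_exons):
            length = int(rng.integers(100, 251))
            # the intron downstream of the slot must hold the alternative exon
            intron = int(rng.integers(700, 1101)) if ei == slot else int(
                rng.integers(250, 801)
            )
            backbone.append((pos, pos + length - 1))
            if ei == slot:
                y_len = int(rng.integers(120, 200))
                y_start = pos + length - 1 + 250
                alt_exon = (y_start, y_start + y_len - 1)
            pos = pos + length + intron
        donor_ext = int(rng.integers(60, 120))
        alt_donor = bool(rng.integers(0, 2))
        strand = "+" if rng.integers(0, 2) else "-"
        chains = _variant_chains(
            backbone, slot, isoforms_per_locus, alt_donor, alt_exon, donor_ext
        )
        total = 10 ** rng.uniform(1.5, 1.9)
        shares = rng.uniform(0.7, 1.0, size=len(chains))
        shares /= shares.sum()
        for ti, (chain, share) in enumerate(zip(chains, shares), start=1):
            transcripts.append(
                TruthTranscript(
                    transcript_id=f"truth.{li}.{ti}",
                    gene_id=f"truth.{li}",
                    chrom=chrom,
                    strand=strand,
                    exons=chain,
                    expression=float(total * share),
                )
            )
        cursor = pos + 8_000
    genome = {chrom: cursor + 200_000}
    return TruthSet(genome=genome, transcripts=tuple(transcripts), rng_seed=rng_seed)


def make_linear_truth(
    n_exons: int = 6,
    rng_seed: int = 0,
    chrom: str = "chr1",
    exon_len: int = 400,
    intron_len: int = 500,
    expression: float = 60.0,
) -> TruthSet:
    """A single multi-exon transcript with regular geometry, convenient for
    constructing complementary junction-dropout scenarios."""
    exons = tuple(
        (10_000 + i * (exon_len + intron_len), 10_000 + i * (exon_len + intron_len) + exon_len - 1)
        for i in range(n_exons)
    )
    tx = TruthTranscript(
        transcript_id="truth.1.1",
        gene_id="truth.1",
        chrom=chrom,
        strand="+",
        exons=exons,
        expression=expression,
    )
    return TruthSet(
        genome={chrom: exons[-1][1] + 200_000}, transcripts=(tx,), rng_seed=rng_seed
    )


def _project(exons: tuple[Interval, ...], t_start: int, length: int) -> tuple[Interval, ...]:
    """Project a transcript-coordinate interval to genomic blocks."""
    blocks: list[Interval] = []
    offset = 0
    remaining = length
    for s, e in exons:
        ex_len = e - s + 1
        if t_start < offset + ex_len and remaining > 0:
            gs = s + max(0, t_start - offset)
            take = min(remaining, e - gs + 1)
            blocks.append((gs, gs + take - 1))
            remaining -= take
        offset += ex_len
        if remaining <= 0:
            break
    return tuple(blocks)


def simulate_fragments(
    truth: TruthSet,
    depth: float = 10.0,
    fragment_len: int = 220,
    read_len: int = 150,
    rng_seed: int = 0,
) -> list[Fragment]:
    """Sample paired-end fragments per transcript proportional to expression.

    ``depth`` scales fragments per kilobase per expression unit.  Starts
    are stratified (evenly spaced with jitter) so junction-spanning counts
    are stable at moderate depth.  The default geometry gives mates an
    80 nt overlap, as in short-insert libraries: the mate-joining rule
    requires the two mates to share at least one splice-graph edge, which
    an inner gap makes impossible.  Reads are longer than the shortest
    exons, so a read can bridge two junctions and mate pairs yield
    multi-node paired paths.  Transcripts shorter than the fragment
    length are skipped with a warning.
    """
    import logging

    if read_len > fragment_len:
        raise ValueError("read_len must be <= fragment_len")
    rng = np.random.default_rng(rng_seed)
    frags: list[Fragment] = []
    for tx in truth.transcripts:
        L = tx.length
        if L < fragment_len:
            logging.getLogger(__name__).warning(
                "%s shorter than fragment length; skipped", tx.transcript_id
            )
            continue
        n = int(round(tx.expression * depth * L / 1000.0))
        if n <= 0:
            continue
        span = L - fragment_len + 1
        starts = ((np.arange(n) + rng.random(n)) * span / n).astype(int)
        for i, t0 in enumerate(starts):
            m1 = _project(tx.exons, int(t0), read_len)
            m2 = _project(tx.exons, int(t0) + fragment_len - read_len, read_len)
            frags.append(
                Fragment(
                    frag_id=f"{tx.transcript_id}:f{i}",
                    chrom=tx.chrom,
                    strand=tx.strand,
                    mate1_blocks=m1,
                    mate2_blocks=m2,
                )
            )
    return frags


def _cigar(blocks: tuple[Interval, ...]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i > 0:
            parts.append(f"{s - blocks[i - 1][1] - 1}N")
        parts.append(f"{e - s + 1}M")
    return "".join(parts)


def emulate_aligner(
    fragments: list[Fragment],
    profile: AlignerProfile,
    genome: dict[str, int],
    out_path: str,
    rng_seed: int = 0,
) -> None:
    """Write a valid coordinate-sorted SAM for one emulated aligner.

    Fragments with a mate spanning any dropout junction are omitted
    entirely; a ``readset_jitter`` fraction of the remaining
    junction-spanning fragments are renamed with an aligner-specific
    suffix (so supporting read sets differ across aligners); a
    ``multimap_frac`` fraction is duplicated to a decoy region with NH=2.
    """
    rng = np.random.default_rng(rng_seed)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": length} for name, length in sorted(genome.items())
            ],
            "PG": [{"ID": profile.aligner_id, "PN": profile.aligner_id}],
        }
    )
    records: list[tuple[int, int, pysam.AlignedSegment]] = []

    def add(chrom, pos, qname, flag, blocks, nh, strand, mpos):
        read_len = sum(e - s + 1 for s, e in blocks)
        a = pysam.AlignedSegment(header)
        a.query_name = qname
        a.flag = flag
        a.reference_name = chrom
        a.reference_start = pos - 1
        a.mapping_quality = 60 if nh == 1 else 1
        a.cigarstring = _cigar(blocks)
        a.next_reference_name = chrom
        a.next_reference_start = mpos - 1
        a.template_length = 0
        a.query_sequence = "N" * read_len
        tags = [("NH", nh)]
        if len(blocks) > 1:
            tags.append(("XS", strand))
        a.set_tags(tags)
        records.append((a.reference_id, pos, a))

    decoy_base = max(genome.values()) - 90_000
    decoy_idx = 0
    for frag in fragments:
        if frag.junctions() & profile.junction_dropout:
            continue
        qname = frag.frag_id
        if frag.junctions() and profile.readset_jitter > 0:
            if rng.random() < profile.readset_jitter:
                qname = f"{frag.frag_id}:{profile.aligner_id}"
        multimap = profile.multimap_frac > 0 and rng.random() < profile.multimap_frac
        nh = 2 if multimap else 1
        p1, p2 = frag.mate1_blocks[0][0], frag.mate2_blocks[0][0]
        # flags: paired + proper + mate-reverse/reverse + first/second
        add(frag.chrom, p1, qname, 0x1 | 0x2 | 0x20 | 0x40, frag.mate1_blocks, nh, frag.strand, p2)
        add(frag.chrom, p2, qname, 0x1 | 0x2 | 0x10 | 0x80, frag.mate2_blocks, nh, frag.strand, p1)
        if multimap:
            dpos = decoy_base + (decoy_idx % 200) * 400
            decoy_idx += 1
            rl1 = sum(e - s + 1 for s, e in frag.mate1_blocks)
            rl2 = sum(e - s + 1 for s, e in frag.mate2_blocks)
            add(frag.chrom, dpos, qname, 0x1 | 0x20 | 0x40 | 0x100, ((dpos, dpos + rl1 - 1),), nh, frag.strand, dpos)
            add(frag.chrom, dpos, qname, 0x1 | 0x10 | 0x80 | 0x100, ((dpos, dpos + rl2 - 1),), nh, frag.strand, dpos)
    records.sort(key=lambda r: (r[0], r[1]))
    with pysam.AlignmentFile(out_path, "w", header=header) as out:
        for _, _, seg in records:
            out.write(seg)


def write_truth_gtf(truth: TruthSet, path: str) -> None:
    transcripts = [
        Transcript(
            chrom=tx.chrom,
            strand=tx.strand,
            exons=tx.exons,
            gene_id=tx.gene_id,
            transcript_id=tx.transcript_id,
            cov=tx.expression,
        )
        for tx in truth.transcripts
    ]
    write_gtf(transcripts, path)
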