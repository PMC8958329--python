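"""Read spliced alignments from SAM/BAM and cluster them into gene loci.

Each input file carries one aligner's view of the same RNA-seq sample.
Alignments are reduced to genomic blocks (1-based inclusive intervals)
plus the splice junctions between them; a read reported at N sites
(``NH:i:N``) contributes 1/N to every weight it supports, so its total
contribution over all sites is exactly one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import pysam

logger = logging.getLogger(__name__)

# CIGAR opcodes that consume reference bases into the current block.
# Deletions (D) stay inside a block: the reference bases are part of the
# exon for segmentation purposes.  N closes a block and opens the next.
_BLOCK_OPS = {0, 2, 7, 8}  # M, D, =, X
_SKIP_OPS = {1, 4, 5, 6}  # I, S, H, P: no reference consumed
_N_OP = 3
_KNOWN_OPS = _BLOCK_OPS | _SKIP_OPS | {_N_OP}


class Junction(NamedTuple):
    """A splice junction keyed by its exonic flanks.

    ``donor`` is the last exonic base before the intron, ``acceptor`` the
    first exonic base after it (both 1-based), so the intron occupies
    ``[donor+1, acceptor-1]``.
    """

    chrom: str
    donor: int
    acceptor: int


@dataclass(frozen=True)
class AlignedRead:
    """One mate's alignment: genomic blocks plus bookkeeping."""

    read_id: str
    mate: int  # 1 or 2
    aligner_id: str
    chrom: str
    strand_hint: str | None  # '+'/'-' from the XS tag, None if absent
    blocks: tuple[tuple[int, int], ...]  # 1-based inclusive, sorted
    nh: int = 1

    @property
    def contribution(self) -> float:
        """Weight share of this alignment: 1/NH."""
        return 1.0 / self.nh

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def mate_id(self) -> str:
        """Identifier distinguishing the two mates of one fragment."""
        return f"{self.read_id}/{self.mate}"

    def junctions(self) -> list[Junction]:
        return [
            Junction(self.chrom, self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        ]


@dataclass
class Locus:
    """A maximal genomic region connected by read coverage or spanned introns
    across all aligners."""

    chrom: str
    strand: str  # '+', '-' or '.' (no junction evidence)
    span: tuple[int, int]
    reads: dict[str, list[AlignedRead]] = field(default_factory=dict)
    junction_support: dict[str, dict[Junction, tuple[float, set[str]]]] = field(
        default_factory=dict
    )


def _blocks_from_cigar(pos: int, cigartuples) -> tuple[tuple[int, int], ...] | None:
    """Walk a CIGAR from 1-based ``pos``; return blocks or None on unknown ops."""
    blocks: list[tuple[int, int]] = []
    start = pos
    cur = pos
    for op, length in cigartuples:
        if op in _BLOCK_OPS:
            cur += length
        elif op == _N_OP:
            if cur > start:
                blocks.append((start, cur - 1))
            cur += length
            start = cur
        elif op in _SKIP_OPS:
            continue
        else:
            return None
    if cur > start:
        blocks.append((start, cur - 1))
    return tuple(blocks) if blocks else None


def read_alignments(path: str, aligner_id: str) -> Iterator[AlignedRead]:
    """Stream one :class:`AlignedRead` per reported alignment of a mate.

    Secondary alignments are kept (they carry the 1/NH shares);
    supplementary (chimeric) and unmapped records are dropped.  The input
    must be coordinate-sorted; violation raises ``ValueError``.
    """
    with pysam.AlignmentFile(path, check_sq=False) as af:
        if af.header.nreferences == 0:
            raise ValueError(f"{path}: missing header sequence dictionary (@SQ lines)")
        so = af.header.to_dict().get("HD", {}).get("SO")
        if so is not None and so != "coordinate":
            raise ValueError(f"{path}: not coordinate-sorted (SO:{so})")
        last_tid, last_pos = -1, -1
        for rec in af:
            if rec.is_unmapped or rec.is_supplementary:
                continue
            tid, pos0 = rec.reference_id, rec.reference_start
            if tid < last_tid or (tid == last_tid and pos0 < last_pos):
                raise ValueError(f"{path}: records not coordinate-sorted")
            last_tid, last_pos = tid, pos0
            blocks = _blocks_from_cigar(pos0 + 1, rec.cigartuples or ())
            if blocks is None:
                logger.warning(
                    "%s: skipping %s: unknown CIGAR opcode", path, rec.query_name
                )
                continue
            nh = int(rec.get_tag("NH")) if rec.has_tag("NH") else 1
            xs = rec.get_tag("XS") if rec.has_tag("XS") else None
            yield AlignedRead(
                read_id=rec.query_name,
                mate=2 if rec.is_read2 else 1,
                aligner_id=aligner_id,
                chrom=rec.reference_name,
                strand_hint=xs if xs in ("+", "-") else None,
                blocks=blocks,
                nh=max(1, nh),
            )


def collect_junction_support(
    reads: Iterable[AlignedRead],
) -> dict[Junction, tuple[float, set[str]]]:
    """Sum 1/NH contributions and gather mate ids per junction.

    Each mate spanning a junction counts once; mates are distinguished by
    name + mate flag in the read-id sets.
    """
    support: dict[Junction, tuple[float, set[str]]] = {}
    for read in reads:
        for j in read.junctions():
            w, ids = support.get(j, (0.0, set()))
            if read.mate_id not in ids:
                w += read.contribution
                ids.add(read.mate_id)
            support[j] = (w, ids)
    return support


def _junction_strand_votes(
    reads: Iterable[AlignedRead],
) -> dict[Junction, dict[str, int]]:
    votes: dict[Junction, dict[str, int]] = {}
    for read in reads:
        if read.strand_hint is None:
            continue
        for j in read.junctions():
            votes.setdefault(j, {"+": 0, "-": 0})[read.strand_hint] += 1
    return votes


def _make_locus(chrom: str, reads: list[AlignedRead]) -> Locus:
    strand_counts = {"+": 0, "-": 0}
    for r in reads:
        if r.strand_hint is not None and len(r.blocks) > 1:
            strand_counts[r.strand_hint] += 1
    if strand_counts["+"] == strand_counts["-"] == 0:
        strand = "."
    else:
        strand = "+" if strand_counts["+"] >= strand_counts["-"] else "-"
    by_aligner: dict[str, list[AlignedRead]] = {}
    for r in reads:
        by_aligner.setdefault(r.aligner_id, []).append(r)
    span = (min(r.span[0] for r in reads), max(r.span[1] for r in reads))
    return Locus(
        chrom=chrom,
        strand=strand,
        span=span,
        reads=by_aligner,
        junction_support={
            aid: collect_junction_support(rs) for aid, rs in by_aligner.items()
        },
    )


def _split_by_strand(chrom: str, reads: list[AlignedRead]) -> list[Locus]:
    """Split a read cluster into per-strand loci when the two strands'
    junction sets are disjoint; otherwise keep one locus (majority strand)."""
    votes = _junction_strand_votes(r for r in reads if len(r.blocks) > 1)
    plus = {j for j, v in votes.items() if v["+"] > 0}
    minus = {j for j, v in votes.items() if v["-"] > 0}
    if not plus or not minus or (plus & minus):
        return [_make_locus(chrom, reads)]
    stranded: dict[str, list[AlignedRead]] = {"+": [], "-": []}
    unassigned: list[AlignedRead] = []
    for r in reads:
        if r.strand_hint in ("+", "-"):
            stranded[r.strand_hint].append(r)
        else:
            unassigned.append(r)
    majority = "+" if sum(votes[j]["+"] for j in plus) >= sum(
        votes[j]["-"] for j in minus
    ) else "-"
    stranded[majority].extend(unassigned)
    return [
        _make_locus(chrom, rs) for s, rs in stranded.items() if rs
    ]


def cluster_loci(reads_by_aligner: dict[str, Iterable[AlignedRead]]) -> list[Locus]:
    """Cluster reads from all aligners into maximal connected gene loci.

    Two reads belong to the same locus when the union of read spans (blocks
    plus spanned introns) is connected; a gap of >= 1 base that no read
    covers or spans ends a locus.
    """
    by_chrom: dict[str, list[AlignedRead]] = {}
    for aid, reads in reads_by_aligner.items():
        for r in reads:
            by_chrom.setdefault(r.chrom, []).append(r)
    loci: list[Locus] = []
    for chrom in sorted(by_chrom):
        reads = sorted(by_chrom[chrom], key=lambda r: r.span)
        cluster: list[AlignedRead] = []
        cur_end = -1
        for r in reads:
            if cluster and r.span[0] > cur_end + 1:
                loci.extend(_split_by_strand(chrom, cluster))
                cluster = []
                cur_end = -1
            cluster.append(r)
            cur_end = max(cur_end, r.span[1])
        if cluster:
            loci.extend(_split_by_strand(chrom, cluster))
    return loci
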