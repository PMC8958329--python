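"""Intron-chain evaluation: exact matching of predicted vs reference GTF.

A multi-exon prediction is correct iff its ordered intron set equals a
reference transcript's intron chain exactly.  Single-exon transcripts are
scored separately by >= 80% reciprocal overlap and excluded from the
headline multi-exon counts.
"""

from __future__ import annotations

from dataclasses import dataclass

from .gtf import read_exon_chains
from .splice_graph import Interval


@dataclass(frozen=True)
class MatchResult:
    n_correct: int  # multi-exon predictions with an exactly matching chain
    n_predicted: int  # multi-exon predictions
    n_truth: int  # multi-exon reference transcripts
    precision: float
    recall: float
    f_score: float
    single_exon_matched: int
    single_exon_predicted: int
    single_exon_truth: int


def _chain_key(chrom: str, exons: tuple[Interval, ...]) -> tuple:
    introns = tuple(
        (exons[i][1] + 1, exons[i + 1][0] - 1) for i in range(len(exons) - 1)
    )
    return (chrom, introns)


def _strands_compatible(a: str, b: str) -> bool:
    return a == b or a == "." or b == "."


def _reciprocal_overlap(a: Interval, b: Interval) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0] + 1), inter / (b[1] - b[0] + 1))


def intron_chain_match(predicted_gtf: str, truth_gtf: str) -> MatchResult:
    """Score predictions against a reference annotation.

    precision = correct / predicted multi-exon, recall = matched / truth
    multi-exon, F-score = 2*p*r/(p+r).
    """
    pred = read_exon_chains(predicted_gtf)
    truth = read_exon_chains(truth_gtf)

    pred_multi = {t: v for t, v in pred.items() if len(v[2]) > 1}
    truth_multi = {t: v for t, v in truth.items() if len(v[2]) > 1}
    truth_keys: dict[tuple, list[str]] = {}
    for tid, (chrom, strand, exons) in truth_multi.items():
        truth_keys.setdefault(_chain_key(chrom, exons), []).append(tid)

    n_correct = 0
    matched_truth: set[str] = set()
    for chrom, strand, exons in pred_multi.values():
        hits = [
            tid
            for tid in truth_keys.get(_chain_key(chrom, exons), [])
            if _strands_compatible(strand, truth_multi[tid][1])
        ]
        if hits:
            n_correct += 1
            matched_truth.update(hits)

    pred_single = [v for v in pred.values() if len(v[2]) == 1]
    truth_single = [v for v in truth.values() if len(v[2]) == 1]
    single_matched = 0
    for chrom, strand, exons in pred_single:
        for tchrom, tstrand, texons in truth_single:
            if (
                chrom == tchrom
                and _strands_compatible(strand, tstrand)
                and _reciprocal_overlap(exons[0], texons[0]) >= 0.8
            ):
                single_matched += 1
                break

    n_pred, n_truth = len(pred_multi), len(truth_multi)
    precision = n_correct / n_pred if n_pred else 0.0
    recall = len(matched_truth) / n_truth if n_truth else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MatchResult(
        n_correct=n_correct,
        n_predicted=n_pred,
        n_truth=n_truth,
        precision=precision,
        recall=recall,
        f_score=f,
        single_exon_matched=single_matched,
        single_exon_predicted=len(pred_single),
        single_exon_truth=len(truth_single),
    )
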