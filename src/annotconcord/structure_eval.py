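"""Gene-structure accuracy: TP/FP/FN and Sn/Pr/F1 at three matching levels.

Matching semantics
------------------
exon
    Distinct coding intervals ``(seq_id, start, end, strand)``; duplicates
    across transcripts of a set collapse (set semantics).
transcript
    Exact equality of the full coordinate chain including sequence and
    strand — no partial credit, no UTRs.
gene
    A reference gene counts as found (sensitivity) when at least one of its
    transcript chains occurs anywhere in the prediction; a predicted gene
    counts as correct (precision) when at least one of its chains occurs in
    the reference. The two TP counts are asymmetric by construction.

Sn = TP/(TP+FN), Pr = TP/(TP+FP), F1 = 2·Pr·Sn/(Pr+Sn); every ratio with a
zero denominator is reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Set, Tuple

import pandas as pd

from .model import AnnotationSet, GenomicInterval, TranscriptModel

__all__ = [
    "LEVELS",
    "EvalCounts",
    "AccuracyReport",
    "collect_units",
    "evaluate",
    "accuracy_from_counts",
    "trim_stop_codons",
]

LEVELS = ("exon", "transcript", "gene")


@dataclass(frozen=True)
class EvalCounts:
    """Match counts at one level.

    ``tp_predicted`` only differs from ``tp`` at gene level, where the
    true-positive count for precision is taken over predicted genes.
    """

    level: str
    tp: int
    fp: int
    fn: int
    tp_predicted: int | None = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")
        if self.tp_predicted is not None and self.tp_predicted < 0:
            raise ValueError("counts must be non-negative")

    @property
    def tp_for_precision(self) -> int:
        return self.tp if self.tp_predicted is None else self.tp_predicted


def accuracy_from_counts(counts: EvalCounts) -> Tuple[float, float, float]:
    """(sensitivity, precision, F1) from one level's counts."""
    sn = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    tp_pr = counts.tp_for_precision
    pr = tp_pr / (tp_pr + counts.fp) if tp_pr + counts.fp else 0.0
    f1 = 2 * pr * sn / (pr + sn) if pr + sn else 0.0
    return sn, pr, f1


@dataclass(frozen=True)
class AccuracyReport:
    counts: Dict[str, EvalCounts]

    def sn(self, level: str) -> float:
        return accuracy_from_counts(self.counts[level])[0]

    def pr(self, level: str) -> float:
        return accuracy_from_counts(self.counts[level])[1]

    def f1(self, level: str) -> float:
        return accuracy_from_counts(self.counts[level])[2]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level in LEVELS:
            c = self.counts[level]
            sn, pr, f1 = accuracy_from_counts(c)
            rows.append(
                {
                    "level": level,
                    "tp": c.tp,
                    "fp": c.fp,
                    "fn": c.fn,
                    "sn": sn,
                    "pr": pr,
                    "f1": f1,
                }
            )
        return pd.DataFrame(rows)


ExonKey = Tuple[str, int, int, str]
TranscriptKey = Tuple[str, str, Tuple[Tuple[int, int], ...]]


def collect_units(annotation: AnnotationSet, level: str):
    """Canonical matchable units of one annotation at one level.

    exon -> set of interval keys; transcript -> set of chain keys;
    gene -> mapping gene_id -> frozenset of its transcript chain keys.
    """
    if level == "exon":
        return {
            (iv.seq_id, iv.start, iv.end, iv.strand)
            for tx in annotation.transcripts()
            for iv in tx.intervals
        }
    if level == "transcript":
        return {tx.chain_key() for tx in annotation.transcripts()}
    if level == "gene":
        return {
            gene_id: frozenset(tx.chain_key() for tx in txs)
            for gene_id, txs in annotation.genes.items()
        }
    raise ValueError(f"unknown level {level!r}")


def evaluate(reference: AnnotationSet, prediction: AnnotationSet) -> AccuracyReport:
    """Compare a prediction against a reference at all three levels.

    Empty inputs are legal; ratios with empty denominators come out 0.
    """
    counts: Dict[str, EvalCounts] = {}

    for level in ("exon", "transcript"):
        ref_units: Set = collect_units(reference, level)
        pred_units: Set = collect_units(prediction, level)
        counts[level] = EvalCounts(
            level=level,
            tp=len(ref_units & pred_units),
            fp=len(pred_units - ref_units),
            fn=len(ref_units - pred_units),
        )

    ref_genes: Dict[str, FrozenSet[TranscriptKey]] = collect_units(reference, "gene")
    pred_genes: Dict[str, FrozenSet[TranscriptKey]] = collect_units(prediction, "gene")
    ref_chains = frozenset().union(*ref_genes.values()) if ref_genes else frozenset()
    pred_chains = frozenset().union(*pred_genes.values()) if pred_genes else frozenset()
    tp_sn = sum(1 for keys in ref_genes.values() if keys & pred_chains)
    tp_pr = sum(1 for keys in pred_genes.values() if keys & ref_chains)
    counts["gene"] = EvalCounts(
        level="gene",
        tp=tp_sn,
        fp=len(pred_genes) - tp_pr,
        fn=len(ref_genes) - tp_sn,
        tp_predicted=tp_pr,
    )
    return AccuracyReport(counts=counts)


def trim_stop_codons(annotation: AnnotationSet, n_bases: int = 3) -> AnnotationSet:
    """Shorten each transcript's translation-terminal CDS by ``n_bases``.

    GTF dialects disagree on whether the stop codon is part of the terminal
    CDS; trimming both inputs by 3 makes them comparable. The terminal CDS is
    the last interval on '+' strands and the first on '-'. Intervals consumed
    entirely are dropped; a transcript trimmed to nothing is removed.
    """
    if n_bases < 0:
        raise ValueError("n_bases must be >= 0")
    genes = {}
    for gene_id, txs in annotation.genes.items():
        new_txs = []
        for tx in txs:
            intervals = list(tx.intervals)
            remaining = n_bases
            while remaining > 0 and intervals:
                idx = -1 if tx.strand == "+" else 0
                iv = intervals[idx]
                if iv.length > remaining:
                    if tx.strand == "+":
                        intervals[idx] = GenomicInterval(
                            iv.seq_id, iv.start, iv.end - remaining, iv.strand
                        )
                    else:
                        intervals[idx] = GenomicInterval(
                            iv.seq_id, iv.start + remaining, iv.end, iv.strand
                        )
                    remaining = 0
                else:
                    remaining -= iv.length
                    intervals.pop(idx)
            if intervals:
                new_txs.append(
                    TranscriptModel(
                        transcript_id=tx.transcript_id,
                        gene_id=tx.gene_id,
                        intervals=intervals,
                    )
                )
        if new_txs:
            genes[gene_id] = new_txs
    return AnnotationSet(genes=genes, source_label=annotation.source_label)
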