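"""Shared domain types for annotation concordance analyses.

Coordinates are 1-based inclusive throughout (GTF/GFF3 native), so unit keys
printed in reports can be compared directly against the source files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Mapping, Set

__all__ = [
    "ParseError",
    "GenomicInterval",
    "TranscriptModel",
    "AnnotationSet",
    "Term",
    "Ontology",
    "GOAnnotationMap",
    "TRNARecord",
    "NAMESPACE_CODES",
]


class ParseError(ValueError):
    """Malformed input; carries a 1-based line number when one is known."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval on a sequence, 1-based inclusive ends."""

    seq_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}] on {self.seq_id}: "
                "require 1 <= start <= end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class TranscriptModel:
    """One transcript as an ordered chain of non-overlapping intervals.

    Intervals are CDS segments by default (the unit the coding-structure
    benchmarks compare); exon mode is available for annotations without CDS.
    """

    transcript_id: str
    gene_id: str
    intervals: List[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"transcript {self.transcript_id}: no intervals")
        seq_ids = {iv.seq_id for iv in self.intervals}
        strands = {iv.strand for iv in self.intervals}
        if len(seq_ids) > 1 or len(strands) > 1:
            raise ValueError(
                f"transcript {self.transcript_id}: intervals span multiple "
                f"sequences/strands ({seq_ids}, {strands})"
            )
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.start, iv.end))
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping intervals "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )

    @property
    def seq_id(self) -> str:
        return self.intervals[0].seq_id

    @property
    def strand(self) -> str:
        return self.intervals[0].strand

    def chain_key(self) -> tuple:
        """Canonical transcript identity: sequence, strand and the full
        ordered coordinate chain. Exact equality of this key is what makes
        two transcripts "the same" at transcript level."""
        return (
            self.seq_id,
            self.strand,
            tuple((iv.start, iv.end) for iv in self.intervals),
        )


@dataclass
class AnnotationSet:
    """A structural annotation: genes, each with one or more transcripts."""

    genes: Dict[str, List[TranscriptModel]]
    source_label: str = ""

    def __post_init__(self) -> None:
        seen: Set[str] = set()
        for gene_id, txs in self.genes.items():
            for tx in txs:
                if tx.gene_id != gene_id:
                    raise ValueError(
                        f"transcript {tx.transcript_id} keyed under {gene_id} "
                        f"but carries gene_id {tx.gene_id}"
                    )
                if tx.transcript_id in seen:
                    raise ValueError(f"duplicate transcript_id {tx.transcript_id}")
                seen.add(tx.transcript_id)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return sum(len(txs) for txs in self.genes.values())

    def transcripts(self) -> Iterator[TranscriptModel]:
        for txs in self.genes.values():
            yield from txs


NAMESPACE_CODES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


@dataclass(frozen=True)
class Term:
    name: str
    namespace: str  # BP / MF / CC / other
    parents: FrozenSet[str]


@dataclass
class Ontology:
    """An acyclic is_a (optionally + part_of) term graph with named roots.

    Roots are the parentless terms of the loaded graph; for the Gene Ontology
    these are the three namespace roots.
    """

    terms: Dict[str, Term]
    roots: FrozenSet[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        dangling = sorted(
            p for t in self.terms.values() for p in t.parents if p not in self.terms
        )
        if dangling:
            raise ValueError(f"parents reference unknown terms: {dangling}")
        computed_roots = frozenset(
            tid for tid, t in self.terms.items() if not t.parents
        )
        if not self.roots:
            self.roots = computed_roots
        elif self.roots != computed_roots:
            raise ValueError("declared roots do not match parentless terms")
        self._assert_acyclic()

    def _assert_acyclic(self) -> None:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for tid, t in self.terms.items():
            for p in t.parents:
                g.add_edge(tid, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def parents(self, term_id: str) -> FrozenSet[str]:
        return self.terms[term_id].parents

    @classmethod
    def from_edges(
        cls,
        edges: Mapping[str, Set[str]],
        names: Mapping[str, str] | None = None,
        namespaces: Mapping[str, str] | None = None,
    ) -> "Ontology":
        """Build an ontology from a child -> parent-set mapping. Terms that
        appear only as parents are created with no parents of their own."""
        all_ids = set(edges)
        for ps in edges.values():
            all_ids |= set(ps)
        terms = {
            tid: Term(
                name=(names or {}).get(tid, tid),
                namespace=(namespaces or {}).get(tid, "other"),
                parents=frozenset(edges.get(tid, frozenset())),
            )
            for tid in sorted(all_ids)
        }
        return cls(terms=terms)


@dataclass
class GOAnnotationMap:
    """protein id -> non-empty set of GO term ids, for one pipeline.

    Proteins without any term are simply absent; coverage statistics rest on
    that convention.
    """

    assignments: Dict[str, Set[str]]
    pipeline_label: str = ""
    n_invalid_tokens: int = 0

    def __post_init__(self) -> None:
        empty = [p for p, terms in self.assignments.items() if not terms]
        if empty:
            raise ValueError(f"proteins with empty term sets: {empty[:5]}")

    def __len__(self) -> int:
        return len(self.assignments)

    def proteins(self) -> Set[str]:
        return set(self.assignments)


@dataclass
class TRNARecord:
    """One tRNA prediction row. begin > end encodes the reverse strand."""

    species: str
    seq_name: str
    begin: int
    end: int
    isotype: str
    anticodon: str
    score: float
    is_pseudo: bool
    intron_count: int
    note: str = ""

    def __post_init__(self) -> None:
        if self.begin == self.end:
            raise ValueError("tRNA record with begin == end")
        if self.intron_count < 0:
            raise ValueError("negative intron count")

    @property
    def span_bp(self) -> int:
        return abs(self.end - self.begin) + 1
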