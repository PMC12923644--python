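"""Readers and writers for the external formats the toolkit touches.

GTF/GFF3 rows are parsed with gffutils' single-line feature parser; the
gene -> transcript -> interval hierarchy, the error rules and the line-number
diagnostics are assembled here. OBO ingestion goes through obonet, newick
through dendropy (see tree.py), FASTA counting through Bio.SeqIO.

All readers accept either a text stream or a path; gzip-compressed paths
(``*.gz``) are read transparently.
"""

from __future__ import annotations

import gzip
import io
import re
import warnings
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Set, Tuple, Union

import obonet
import pandas as pd
from gffutils.feature import feature_from_line

from .model import (
    NAMESPACE_CODES,
    AnnotationSet,
    GenomicInterval,
    GOAnnotationMap,
    Ontology,
    ParseError,
    Term,
    TranscriptModel,
    TRNARecord,
)
from .tree import PhyloTree, parse_newick, write_newick  # re-exported

__all__ = [
    "parse_gtf",
    "parse_gff3",
    "parse_newick",
    "write_newick",
    "parse_obo",
    "parse_go_map",
    "parse_trnascan",
    "decorate_terms",
    "write_tsv_report",
    "count_fasta_records",
    "fasta_lengths",
]

TextSource = Union[str, Path, io.TextIOBase, Iterable[str]]

GO_TOKEN_RE = re.compile(r"^GO:\d{7}$")


def _is_path(source: TextSource) -> bool:
    if isinstance(source, Path):
        return True
    if isinstance(source, str) and source and "\n" not in source:
        return Path(source).is_file()
    return False


def _as_lines(source: TextSource) -> Iterator[str]:
    if _is_path(source):
        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            yield from fh
    elif isinstance(source, str):
        yield from io.StringIO(source)
    else:
        yield from source


def _numbered_rows(source: TextSource) -> Iterator[Tuple[int, str]]:
    for lineno, raw in enumerate(_as_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        yield lineno, line


def _parse_feature(line: str, lineno: int):
    try:
        feature = feature_from_line(line)
    except Exception as exc:
        raise ParseError(f"malformed feature row: {exc}", lineno) from exc
    return feature


def _check_row(feature, lineno: int) -> None:
    if feature.start is None or feature.end is None:
        raise ParseError("missing coordinates", lineno)
    if feature.start > feature.end:
        raise ParseError(
            f"start {feature.start} > end {feature.end}", lineno
        )
    if feature.strand not in ("+", "-"):
        raise ParseError(
            f"unstranded feature (strand {feature.strand!r}) cannot be matched",
            lineno,
        )


def _build_annotation(
    rows: Dict[str, Tuple[str, List[GenomicInterval]]], source_label: str
) -> AnnotationSet:
    genes: Dict[str, List[TranscriptModel]] = {}
    for tx_id, (gene_id, intervals) in rows.items():
        tx = TranscriptModel(transcript_id=tx_id, gene_id=gene_id, intervals=intervals)
        genes.setdefault(gene_id, []).append(tx)
    return AnnotationSet(genes=genes, source_label=source_label)


def parse_gtf(
    source: TextSource, feature_kind: str = "CDS", source_label: str = ""
) -> AnnotationSet:
    """Read a GTF stream, grouping rows of ``feature_kind`` (CDS or exon)
    into transcripts by their ``transcript_id``/``gene_id`` attributes.

    Rows of other feature types and comment lines are ignored. Selected rows
    must be stranded and carry both attributes; violations raise
    :class:`ParseError` naming the offending line.
    """
    if feature_kind not in ("CDS", "exon"):
        raise ValueError(f"feature_kind must be CDS or exon, got {feature_kind!r}")
    rows: Dict[str, Tuple[str, List[GenomicInterval]]] = {}
    for lineno, line in _numbered_rows(source):
        feature = _parse_feature(line, lineno)
        if feature.featuretype != feature_kind:
            continue
        _check_row(feature, lineno)
        attrs = feature.attributes
        gene_ids = attrs.get("gene_id", [])
        tx_ids = attrs.get("transcript_id", [])
        if not gene_ids or not tx_ids:
            missing = "gene_id" if not gene_ids else "transcript_id"
            raise ParseError(f"{feature_kind} row lacks {missing} attribute", lineno)
        interval = GenomicInterval(
            seq_id=feature.seqid,
            start=feature.start,
            end=feature.end,
            strand=feature.strand,
        )
        gene_id, tx_id = gene_ids[0], tx_ids[0]
        if tx_id in rows and rows[tx_id][0] != gene_id:
            raise ParseError(
                f"transcript {tx_id} assigned to two genes "
                f"({rows[tx_id][0]}, {gene_id})",
                lineno,
            )
        rows.setdefault(tx_id, (gene_id, []))[1].append(interval)
    return _build_annotation(rows, source_label)


_TRANSCRIPT_TYPES = {"mRNA", "transcript"}


def parse_gff3(
    source: TextSource, feature_kind: str = "CDS", source_label: str = ""
) -> Tuple[AnnotationSet, GOAnnotationMap]:
    """Read a GFF3 stream with ID/Parent hierarchy.

    Returns the structural annotation plus a map of any ``Ontology_term``
    attributes found on gene or transcript rows, keyed by transcript id
    (gene-level terms propagate to every transcript of the gene). The map is
    empty when no such attributes are present.
    """
    if feature_kind not in ("CDS", "exon"):
        raise ValueError(f"feature_kind must be CDS or exon, got {feature_kind!r}")
    tx_to_gene: Dict[str, str] = {}
    gene_ids: Set[str] = set()
    parent_of: Dict[str, str] = {}
    tx_intervals: Dict[str, List[Tuple[int, GenomicInterval]]] = {}
    ontology_terms: Dict[str, Set[str]] = {}  # keyed by gene or transcript ID
    pending: List[Tuple[int, str, List[str]]] = []  # (lineno, type, parents)

    for lineno, line in _numbered_rows(source):
        feature = _parse_feature(line, lineno)
        ftype = feature.featuretype
        attrs = feature.attributes
        fid = attrs.get("ID", [None])[0]
        parents = list(attrs.get("Parent", []))
        if ftype == "gene":
            if fid is None:
                raise ParseError("gene row lacks ID attribute", lineno)
            gene_ids.add(fid)
            if parents:
                parent_of[fid] = parents[0]
            terms = set(attrs.get("Ontology_term", []))
            if terms:
                ontology_terms.setdefault(fid, set()).update(terms)
        elif ftype in _TRANSCRIPT_TYPES:
            if fid is None:
                raise ParseError(f"{ftype} row lacks ID attribute", lineno)
            if not parents:
                raise ParseError(f"{ftype} row lacks Parent attribute", lineno)
            tx_to_gene[fid] = parents[0]
            parent_of[fid] = parents[0]
            pending.append((lineno, ftype, parents))
            terms = set(attrs.get("Ontology_term", []))
            if terms:
                ontology_terms.setdefault(fid, set()).update(terms)
        elif ftype == feature_kind:
            _check_row(feature, lineno)
            if not parents:
                raise ParseError(f"{feature_kind} row lacks Parent attribute", lineno)
            interval = GenomicInterval(
                seq_id=feature.seqid,
                start=feature.start,
                end=feature.end,
                strand=feature.strand,
            )
            for parent in parents:
                tx_intervals.setdefault(parent, []).append((lineno, interval))

    # referential integrity: every Parent must name a defined feature
    known = gene_ids | set(tx_to_gene)
    for child, parent in parent_of.items():
        if parent not in known:
            raise ParseError(f"Parent={parent} of {child} is not a defined ID")
    for tx_id in tx_intervals:
        if tx_id not in tx_to_gene:
            lineno = tx_intervals[tx_id][0][0]
            raise ParseError(
                f"Parent={tx_id} does not name a transcript feature", lineno
            )
    # cycle detection over the Parent chain
    for start in parent_of:
        seen = {start}
        node = start
        while node in parent_of:
            node = parent_of[node]
            if node in seen:
                raise ParseError(f"cyclic Parent chain involving {node}")
            seen.add(node)

    rows: Dict[str, Tuple[str, List[GenomicInterval]]] = {
        tx_id: (tx_to_gene[tx_id], [iv for _, iv in pairs])
        for tx_id, pairs in tx_intervals.items()
    }
    annotation = _build_annotation(rows, source_label)

    go_assignments: Dict[str, Set[str]] = {}
    for tx_id, gene_id in tx_to_gene.items():
        terms = set(ontology_terms.get(tx_id, set()))
        terms |= ontology_terms.get(gene_id, set())
        if terms:
            go_assignments[tx_id] = terms
    go_map = GOAnnotationMap(assignments=go_assignments, pipeline_label=source_label)
    return annotation, go_map


def parse_obo(source: TextSource, include_part_of: bool = False) -> Ontology:
    """Load an OBO ontology ([Term] stanzas; is_a, optionally part_of).

    Obsolete terms are skipped. Namespaces are coded BP/MF/CC by their
    standard names, anything else as "other". Roots are the parentless terms
    of the loaded graph.
    """
    if _is_path(source):
        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        handle = opener(path, "rt")
    elif isinstance(source, str):
        handle = io.StringIO(source)
    else:
        handle = source
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        graph = obonet.read_obo(handle, ignore_obsolete=True)

    relations = {"is_a"} | ({"part_of"} if include_part_of else set())
    dangling = sorted(n for n, data in graph.nodes(data=True) if "name" not in data)
    if dangling:
        raise ParseError(f"is_a/relationship edges to unknown ids: {dangling}")

    parents: Dict[str, Set[str]] = {tid: set() for tid in graph.nodes}
    for child, parent, key in graph.edges(keys=True):
        if key in relations:
            parents[child].add(parent)

    terms = {}
    for tid, data in graph.nodes(data=True):
        ns = NAMESPACE_CODES.get(data.get("namespace", ""), "other")
        terms[tid] = Term(
            name=data.get("name", tid), namespace=ns, parents=frozenset(parents[tid])
        )
    try:
        return Ontology(terms=terms)
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


_GO_SOURCE_SUFFIX = re.compile(r"\((.*?)\)$")

# standard InterProScan TSV: GO terms live in the 14th column
_IPS_GO_COLUMN = 13


def _collect_tokens(raw_tokens: Iterable[str]) -> Tuple[Set[str], int]:
    valid: Set[str] = set()
    n_invalid = 0
    for token in raw_tokens:
        token = _GO_SOURCE_SUFFIX.sub("", token.strip())
        if not token or token in ("-", ""):
            continue
        if GO_TOKEN_RE.match(token):
            valid.add(token)
        else:
            n_invalid += 1
    return valid, n_invalid


def parse_go_map(
    source: TextSource, dialect: str = "two_column", pipeline_label: str = ""
) -> GOAnnotationMap:
    """Read protein -> GO-term assignments.

    Dialects: ``two_column`` (protein TAB comma/pipe-separated GO ids),
    ``interproscan_tsv`` (standard InterProScan output; GO ids taken from the
    GO column, ``(source)`` suffixes stripped), ``gff3_ontology_term``
    (delegates to :func:`parse_gff3`). Tokens that are not ``GO:`` + 7 digits
    are skipped with a warning; the skip count is carried on the result.
    """
    if dialect == "gff3_ontology_term":
        _, go_map = parse_gff3(source)
        go_map.pipeline_label = pipeline_label or go_map.pipeline_label
        return go_map

    assignments: Dict[str, Set[str]] = {}
    n_invalid = 0
    if dialect == "two_column":
        for lineno, line in _numbered_rows(source):
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError("expected protein TAB go-ids", lineno)
            protein = parts[0].strip()
            tokens = re.split(r"[,|]", parts[1])
            terms, bad = _collect_tokens(tokens)
            n_invalid += bad
            if terms:
                assignments.setdefault(protein, set()).update(terms)
    elif dialect == "interproscan_tsv":
        for lineno, line in _numbered_rows(source):
            parts = line.split("\t")
            if len(parts) <= _IPS_GO_COLUMN:
                continue  # row without a GO column contributes nothing
            protein = parts[0].strip()
            terms, bad = _collect_tokens(parts[_IPS_GO_COLUMN].split("|"))
            n_invalid += bad
            if terms:
                assignments.setdefault(protein, set()).update(terms)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if n_invalid:
        warnings.warn(
            f"skipped {n_invalid} malformed GO tokens while reading "
            f"{dialect} input",
            stacklevel=2,
        )
    return GOAnnotationMap(
        assignments=assignments,
        pipeline_label=pipeline_label,
        n_invalid_tokens=n_invalid,
    )


def parse_trnascan(source: TextSource, species: str = "") -> List[TRNARecord]:
    """Read tRNAscan-SE tabular output (3 header lines, then whitespace-
    delimited rows).

    A record is a pseudogene when its note column contains "pseudo"; its
    intron count is 1 when both intron bounds are nonzero, else 0.
    """
    records: List[TRNARecord] = []
    for lineno, line in enumerate(_as_lines(source), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        head = line.split("\t")[0].strip().lower()
        if head.startswith(("sequence", "name", "--")):
            continue  # header block
        parts = line.split()
        if len(parts) < 9:
            raise ParseError(
                f"expected at least 9 columns, got {len(parts)}", lineno
            )
        try:
            begin, end = int(parts[2]), int(parts[3])
            intron_begin, intron_end = int(parts[6]), int(parts[7])
            score = float(parts[8])
        except ValueError as exc:
            raise ParseError(f"non-numeric column: {exc}", lineno) from exc
        note = " ".join(parts[9:]) if len(parts) > 9 else ""
        records.append(
            TRNARecord(
                species=species,
                seq_name=parts[0],
                begin=begin,
                end=end,
                isotype=parts[4],
                anticodon=parts[5],
                score=score,
                is_pseudo="pseudo" in note,
                intron_count=1 if (intron_begin != 0 and intron_end != 0) else 0,
                note=note,
            )
        )
    return records


def decorate_terms(ontology: Ontology, go_map: GOAnnotationMap) -> pd.DataFrame:
    """One row per (protein, term) with the term's name and namespace.

    Terms absent from the ontology are decorated name="unknown",
    namespace="other". Output order is protein then term, lexicographic.
    """
    rows = []
    for protein in sorted(go_map.assignments):
        for term_id in sorted(go_map.assignments[protein]):
            if term_id in ontology:
                term = ontology.terms[term_id]
                rows.append((protein, term_id, term.name, term.namespace))
            else:
                rows.append((protein, term_id, "unknown", "other"))
    return pd.DataFrame(
        rows, columns=["protein_id", "term_id", "term_name", "namespace"]
    )


def write_tsv_report(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a rectangular table as TAB-delimited UTF-8 with a header line."""
    table.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def count_fasta_records(source: Union[str, Path, io.TextIOBase]) -> int:
    """Number of records in a (possibly gzipped) FASTA file."""
    return sum(1 for _ in fasta_lengths(source))


def fasta_lengths(source: Union[str, Path, io.TextIOBase]) -> Iterator[int]:
    """Sequence lengths of FASTA records, in file order."""
    from Bio import SeqIO

    if _is_path(source):
        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fasta"):
                yield len(rec.seq)
    else:
        handle = io.StringIO(source) if isinstance(source, str) else source
        for rec in SeqIO.parse(handle, "fasta"):
            yield len(rec.seq)
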