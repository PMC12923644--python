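"""Concordance between two GO-annotation pipelines.

Three views, mirroring how dual functional-annotation runs (e.g. a
similarity-transfer pipeline vs. a domain-based one) are compared:

coverage
    Which proteins does each pipeline annotate at all? Reported as the
    both/only-A/only-B partition and the Jaccard index of the two protein
    sets.
exact agreement
    Among co-annotated proteins, does any identical GO id occur in both term
    sets?
relaxed ontology-aware agreement
    Two terms agree when they share an ancestor reachable within
    ``max_levels`` is_a steps from EACH of them (default 3), and that shared
    ancestor may not be an ontology root. A term is its own ancestor at
    level 0, so exact matches of non-root terms imply relaxed agreement.
    Levels are minimum path lengths in the DAG.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .cohort_stats import median_iqr
from .model import GOAnnotationMap, Ontology

__all__ = [
    "AgreementConfig",
    "AgreementSummary",
    "coverage_jaccard",
    "exact_agree",
    "ancestors_within",
    "relaxed_agree",
    "summarize_pair",
    "summarize_cohort",
]


@dataclass(frozen=True)
class AgreementConfig:
    """Parameters of the relaxed agreement criterion.

    Whether part_of edges participate is decided when the ontology is loaded
    (``parse_obo(include_part_of=...)``); the loaded graph carries a single
    parent relation.
    """

    max_levels: int = 3
    exclude_roots: bool = True

    def __post_init__(self) -> None:
        if self.max_levels < 0:
            raise ValueError("max_levels must be >= 0")


@dataclass
class AgreementSummary:
    n_union: int
    n_both: int
    n_only_a: int
    n_only_b: int
    jaccard: float
    exact_rate: float
    relaxed_rate: float
    per_species: Optional[pd.DataFrame] = None
    cohort: Dict[str, Tuple[float, float, float]] = field(default_factory=dict)


def coverage_jaccard(
    map_a: GOAnnotationMap, map_b: GOAnnotationMap
) -> Tuple[int, int, int, float]:
    """Partition counts and Jaccard of the two annotated-protein sets."""
    a, b = map_a.proteins(), map_b.proteins()
    n_both = len(a & b)
    union = len(a | b)
    jaccard = n_both / union if union else 0.0
    return n_both, len(a - b), len(b - a), jaccard


def exact_agree(terms_a: Set[str], terms_b: Set[str]) -> bool:
    """True iff the two (non-empty) term sets share a GO id."""
    if not terms_a or not terms_b:
        raise ValueError("exact agreement is defined for co-annotated proteins only")
    return bool(terms_a & terms_b)


def ancestors_within(ontology: Ontology, term: str, k: int) -> Dict[str, int]:
    """Ancestors reachable within ``k`` upward steps, with their minimum
    level; the term itself is included at level 0."""
    if term not in ontology:
        raise KeyError(f"unknown term {term}")
    if k < 0:
        raise ValueError("k must be >= 0")
    dist = {term: 0}
    queue = deque([term])
    while queue:
        current = queue.popleft()
        d = dist[current]
        if d == k:
            continue
        for parent in ontology.parents(current):
            if parent not in dist:
                dist[parent] = d + 1
                queue.append(parent)
    return dist


def _candidate_ancestors(
    ontology: Ontology, terms: Iterable[str], config: AgreementConfig
) -> Set[str]:
    out: Set[str] = set()
    for term in terms:
        out.update(ancestors_within(ontology, term, config.max_levels))
    if config.exclude_roots:
        out -= set(ontology.roots)
    return out


def relaxed_agree(
    ontology: Ontology,
    terms_a: Set[str],
    terms_b: Set[str],
    config: AgreementConfig = AgreementConfig(),
) -> bool:
    """True iff some term pair (a, b) shares a permitted ancestor within
    ``config.max_levels`` of both a and b.

    Terms absent from the ontology are ignored; if a side loses all its
    terms that way, the question is ill-posed and a ValueError is raised.
    """
    known_a = {t for t in terms_a if t in ontology}
    known_b = {t for t in terms_b if t in ontology}
    if not terms_a or not terms_b:
        raise ValueError("relaxed agreement is defined for co-annotated proteins only")
    if not known_a or not known_b:
        raise ValueError("no terms found in the ontology on one side")
    anc_a = _candidate_ancestors(ontology, known_a, config)
    anc_b = _candidate_ancestors(ontology, known_b, config)
    return bool(anc_a & anc_b)


def _pair_rates(
    ontology: Ontology,
    map_a: GOAnnotationMap,
    map_b: GOAnnotationMap,
    config: AgreementConfig,
) -> Tuple[int, int, int]:
    """(n_both, n_exact, n_relaxed) over co-annotated proteins. Proteins
    whose terms are all unknown to the ontology on either side count as not
    agreeing under the relaxed criterion."""
    shared = map_a.proteins() & map_b.proteins()
    n_exact = 0
    n_relaxed = 0
    for protein in shared:
        ta, tb = map_a.assignments[protein], map_b.assignments[protein]
        if exact_agree(ta, tb):
            n_exact += 1
        try:
            if relaxed_agree(ontology, ta, tb, config):
                n_relaxed += 1
        except ValueError:
            pass
    return len(shared), n_exact, n_relaxed


def summarize_pair(
    ontology: Ontology,
    map_a: GOAnnotationMap,
    map_b: GOAnnotationMap,
    config: AgreementConfig = AgreementConfig(),
) -> AgreementSummary:
    """Coverage partition plus exact/relaxed agreement rates for one pair of
    pipelines; rates are over co-annotated proteins and reported as 0 when
    there are none."""
    n_both, n_only_a, n_only_b, jaccard = coverage_jaccard(map_a, map_b)
    n_shared, n_exact, n_relaxed = _pair_rates(ontology, map_a, map_b, config)
    return AgreementSummary(
        n_union=n_both + n_only_a + n_only_b,
        n_both=n_both,
        n_only_a=n_only_a,
        n_only_b=n_only_b,
        jaccard=jaccard,
        exact_rate=n_exact / n_shared if n_shared else 0.0,
        relaxed_rate=n_relaxed / n_shared if n_shared else 0.0,
    )


def summarize_cohort(
    species_pairs: Sequence[Tuple[str, GOAnnotationMap, GOAnnotationMap]],
    ontology: Ontology,
    config: AgreementConfig = AgreementConfig(),
    n_proteins: Optional[Dict[str, int]] = None,
) -> AgreementSummary:
    """Per-species rows plus pooled and median/IQR cohort statistics.

    ``n_proteins`` (per-species proteome sizes) enables the coverage
    percentages; pooled statistics treat the concatenation of all species
    (ids made species-unique) as one universe.
    """
    if not species_pairs:
        raise ValueError("cohort must contain at least one species")
    rows: List[dict] = []
    pooled_a: Dict[str, Set[str]] = {}
    pooled_b: Dict[str, Set[str]] = {}
    for species, map_a, map_b in species_pairs:
        summary = summarize_pair(ontology, map_a, map_b, config)
        row = {
            "species": species,
            "n_union": summary.n_union,
            "n_both": summary.n_both,
            "n_only_a": summary.n_only_a,
            "n_only_b": summary.n_only_b,
            "jaccard": summary.jaccard,
            "exact_rate": summary.exact_rate,
            "relaxed_rate": summary.relaxed_rate,
        }
        if n_proteins is not None:
            total = n_proteins[species]
            row["coverage_a_pct"] = 100.0 * len(map_a) / total if total else 0.0
            row["coverage_b_pct"] = 100.0 * len(map_b) / total if total else 0.0
        rows.append(row)
        for pid, terms in map_a.assignments.items():
            pooled_a[f"{species}:{pid}"] = terms
        for pid, terms in map_b.assignments.items():
            pooled_b[f"{species}:{pid}"] = terms

    per_species = pd.DataFrame(rows)
    pooled = summarize_pair(
        ontology,
        GOAnnotationMap(pooled_a, map_a.pipeline_label),
        GOAnnotationMap(pooled_b, map_b.pipeline_label),
        config,
    )
    cohort = {
        col: median_iqr(per_species[col].tolist())
        for col in per_species.columns
        if col != "species"
    }
    pooled.per_species = per_species
    pooled.cohort = cohort
    return pooled
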