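"""Deterministic synthetic-data generators with machine-readable truth.

Every generator is a pure function of its parameters and an explicit seed
(``random.Random`` only, so regeneration is byte-identical), and emits both
the input text an analysis operation would read and a :class:`TruthRecord`
whose expected values are computed constructively, with plain set/arithmetic
logic local to this module — never by calling the analysis code under test.

The defaults describe the kind of cohort the toolkit targets: a
200-species insect annotation set with dual GO pipelines whose coverage
partition is 56.5% both / 39.4% only-A / 4.1% only-B, 80.8% exact and 94.2%
relaxed term agreement among co-annotated proteins, tRNA complements with a
median of ~489 confirmed tRNAs and ~3.6 per Mbp density, and a pair of
200-leaf species trees differing in ~5% of their splits.
"""

from __future__ import annotations

import copy
import math
import random
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

from .model import GOAnnotationMap, Ontology
from .tree import PhyloTree, TreeNode, write_newick

__all__ = [
    "TruthRecord",
    "make_annotation_pair",
    "make_taxonomy_tree",
    "make_ontology",
    "make_go_maps",
    "make_tree_pair",
    "make_trna_table",
    "go_map_to_two_column",
]


@dataclass
class TruthRecord:
    generator: str
    seed: int
    values: Dict[str, object] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [f"generator={self.generator}", f"seed={self.seed}"]
        for key in sorted(self.values):
            lines.append(f"{key}={self.values[key]}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "TruthRecord":
        values: Dict[str, object] = {}
        generator, seed = "", 0
        for line in text.splitlines():
            if not line.strip():
                continue
            key, _, value = line.partition("=")
            if key == "generator":
                generator = value
            elif key == "seed":
                seed = int(value)
            else:
                values[key] = value
        return cls(generator=generator, seed=seed, values=values)


# ---------------------------------------------------------------------------
# annotation pairs with known TP/FP/FN structure


def _gtf_lines(
    genes: Dict[str, Dict[str, List[Tuple[str, int, int, str]]]], source: str
) -> str:
    lines = []
    for gene_id in sorted(genes):
        for tx_id in sorted(genes[gene_id]):
            for seq_id, start, end, strand in genes[gene_id][tx_id]:
                lines.append(
                    f"{seq_id}\t{source}\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
                    f'gene_id "{gene_id}"; transcript_id "{tx_id}";'
                )
    return "\n".join(lines) + "\n"


def _unit_sets(genes):
    """Exon / chain / gene-key unit sets via direct set logic."""
    exons, chains = set(), set()
    gene_keys = {}
    for gene_id, txs in genes.items():
        keys = set()
        for intervals in txs.values():
            for iv in intervals:
                exons.add(iv)
            seq_id, strand = intervals[0][0], intervals[0][3]
            chain = (seq_id, strand, tuple((s, e) for _, s, e, _ in intervals))
            chains.add(chain)
            keys.add(chain)
        gene_keys[gene_id] = frozenset(keys)
    return exons, chains, gene_keys


def make_annotation_pair(
    seed: int,
    n_genes: int = 30,
    frac_exact_transcripts: float = 0.6,
    perturbations: Sequence[str] = ("boundary_shift", "exon_drop", "novel_gene"),
) -> Tuple[str, str, TruthRecord]:
    """A reference GTF, a prediction GTF derived from it, and exact truth.

    A known fraction of reference transcripts is copied verbatim into the
    prediction; the rest are perturbed (CDS boundary shifts, dropped CDS) or
    omitted when no per-transcript perturbation is enabled. ``novel_gene``
    adds extra predicted genes with no reference counterpart. Truth TP/FP/FN
    at exon, transcript and gene level are recounted from the emitted unit
    sets inside this function.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0.0 <= frac_exact_transcripts <= 1.0:
        raise ValueError("frac_exact_transcripts must be in [0, 1]")
    known = {"boundary_shift", "exon_drop", "novel_gene"}
    if set(perturbations) - known:
        raise ValueError(f"unknown perturbations: {set(perturbations) - known}")
    rng = random.Random(seed)
    chroms = ["chr1", "chr2", "chr3"]
    cursor = {c: 1000 for c in chroms}

    def new_backbone(chrom: str, strand: str, n_exons: int):
        pos = cursor[chrom]
        backbone = []
        for _ in range(n_exons):
            length = rng.randint(50, 300)
            backbone.append((chrom, pos, pos + length - 1, strand))
            pos += length + rng.randint(30, 200)
        cursor[chrom] = pos + 1000  # slack so perturbed bounds cannot collide
        return backbone

    ref: Dict[str, Dict[str, List[Tuple[str, int, int, str]]]] = {}
    for i in range(n_genes):
        chrom = rng.choice(chroms)
        strand = rng.choice("+-")
        backbone = new_backbone(chrom, strand, rng.randint(1, 5))
        slices = [(0, 0), (1, 0), (0, 1), (1, 1)]
        chains = []
        for a, b in slices:
            sub = backbone[a : len(backbone) - b]
            if sub and sub not in chains:
                chains.append(sub)
        n_tx = rng.randint(1, min(3, len(chains)))
        gene_id = f"g{i:04d}"
        ref[gene_id] = {
            f"{gene_id}.t{j + 1}": chains[j] for j in range(n_tx)
        }

    per_tx = [p for p in perturbations if p != "novel_gene"]
    pred: Dict[str, Dict[str, List[Tuple[str, int, int, str]]]] = {}
    for i, gene_id in enumerate(sorted(ref)):
        out_txs = {}
        for j, tx_id in enumerate(sorted(ref[gene_id])):
            intervals = list(ref[gene_id][tx_id])
            if rng.random() < frac_exact_transcripts:
                out_txs[f"pg{i:04d}.t{j + 1}"] = intervals
                continue
            if not per_tx:
                continue  # transcript omitted from the prediction
            kind = rng.choice(per_tx)
            if kind == "exon_drop" and len(intervals) == 1:
                kind = "boundary_shift"
            if kind == "exon_drop":
                intervals.pop(rng.randrange(len(intervals)))
            else:
                k = rng.randrange(len(intervals))
                seq_id, start, end, strand = intervals[k]
                intervals[k] = (seq_id, start, end + rng.randint(1, 10), strand)
            out_txs[f"pg{i:04d}.t{j + 1}"] = intervals
        if out_txs:
            pred[f"pg{i:04d}"] = out_txs
    if "novel_gene" in perturbations:
        n_novel = max(1, round(0.1 * n_genes))
        for k in range(n_novel):
            chrom = rng.choice(chroms)
            strand = rng.choice("+-")
            backbone = new_backbone(chrom, strand, rng.randint(1, 4))
            gene_id = f"pnovel{k:03d}"
            pred[gene_id] = {f"{gene_id}.t1": backbone}

    ref_exons, ref_chains, ref_gene_keys = _unit_sets(ref)
    pred_exons, pred_chains, pred_gene_keys = _unit_sets(pred)
    values = {
        "ref_n_genes": len(ref),
        "ref_n_transcripts": sum(len(t) for t in ref.values()),
        "ref_n_exon_units": len(ref_exons),
        "pred_n_genes": len(pred),
        "pred_n_transcripts": sum(len(t) for t in pred.values()),
        "exon_tp": len(ref_exons & pred_exons),
        "exon_fp": len(pred_exons - ref_exons),
        "exon_fn": len(ref_exons - pred_exons),
        "transcript_tp": len(ref_chains & pred_chains),
        "transcript_fp": len(pred_chains - ref_chains),
        "transcript_fn": len(ref_chains - pred_chains),
        "gene_tp_sn": sum(1 for ks in ref_gene_keys.values() if ks & pred_chains),
        "gene_tp_pr": sum(1 for ks in pred_gene_keys.values() if ks & ref_chains),
    }
    values["gene_fn"] = len(ref_gene_keys) - values["gene_tp_sn"]
    values["gene_fp"] = len(pred_gene_keys) - values["gene_tp_pr"]
    truth = TruthRecord(generator="annotation_pair", seed=seed, values=values)
    return _gtf_lines(ref, "ref"), _gtf_lines(pred, "pred"), truth


# ---------------------------------------------------------------------------
# taxonomy trees with integer level-count branch lengths


def make_taxonomy_tree(
    seed: int, n_leaves: int = 10, max_depth: int = 4
) -> Tuple[str, TruthRecord]:
    """A random rooted tree with integer branch lengths in [1, max_depth]
    (levels spanned per branch), as newick text plus its total length."""
    if n_leaves < 2:
        raise ValueError("n_leaves must be >= 2")
    rng = random.Random(seed)
    nodes = [TreeNode(label=f"T{i:03d}") for i in range(n_leaves)]
    total = 0
    while len(nodes) > 1:
        k = min(len(nodes), rng.randint(2, 3))
        picked = [nodes.pop(rng.randrange(len(nodes))) for _ in range(k)]
        parent = TreeNode()
        for child in picked:
            child.length = rng.randint(1, max_depth)
            total += child.length
            parent.add_child(child)
        nodes.append(parent)
    tree = PhyloTree(nodes[0])
    truth = TruthRecord(
        generator="taxonomy_tree",
        seed=seed,
        values={"n_leaves": n_leaves, "total_length": total},
    )
    return write_newick(tree), truth


# ---------------------------------------------------------------------------
# small acyclic ontologies


_NAMESPACES = ["biological_process", "molecular_function", "cellular_component"]


def make_ontology(
    seed: int, n_terms: int = 40, n_roots: int = 3, edge_density: float = 1.5
) -> Tuple[str, TruthRecord]:
    """A random acyclic is_a ontology as OBO text.

    The first ``n_roots`` terms are roots, each founding one namespace
    component (namespaces cycle BP/MF/CC); every other term attaches to one
    or two earlier terms of the same component, so components only ever meet
    at nothing — distinct namespaces share no ancestors. Truth lists the
    edges and roots.
    """
    if not 1 <= n_roots <= n_terms:
        raise ValueError("need n_terms >= n_roots >= 1")
    rng = random.Random(seed)
    ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    namespace_of: Dict[str, str] = {}
    component: Dict[int, List[str]] = {r: [ids[r]] for r in range(n_roots)}
    for r in range(n_roots):
        namespace_of[ids[r]] = _NAMESPACES[r % len(_NAMESPACES)]
    parents: Dict[str, List[str]] = {tid: [] for tid in ids}
    for i in range(n_roots, n_terms):
        comp = rng.randrange(n_roots)
        candidates = component[comp]
        chosen = [rng.choice(candidates)]
        if len(candidates) > 1 and rng.random() < max(0.0, edge_density - 1.0):
            second = rng.choice([c for c in candidates if c != chosen[0]])
            chosen.append(second)
        parents[ids[i]] = sorted(chosen)
        namespace_of[ids[i]] = namespace_of[ids[comp]]
        component[comp].append(ids[i])

    stanzas = ["format-version: 1.2", "ontology: synthetic", ""]
    for i, tid in enumerate(ids):
        stanzas.append("[Term]")
        stanzas.append(f"id: {tid}")
        stanzas.append(f"name: synthetic term {i}")
        stanzas.append(f"namespace: {namespace_of[tid]}")
        for p in parents[tid]:
            stanzas.append(f"is_a: {p} ! synthetic parent")
        stanzas.append("")
    edges = sorted(f"{child}>{p}" for child, ps in parents.items() for p in ps)
    truth = TruthRecord(
        generator="ontology",
        seed=seed,
        values={
            "n_terms": n_terms,
            "roots": ";".join(ids[:n_roots]),
            "edges": ";".join(edges),
        },
    )
    return "\n".join(stanzas) + "\n", truth


# ---------------------------------------------------------------------------
# paired GO annotation maps with planted coverage and agreement


def make_go_maps(
    seed: int,
    ontology: Ontology,
    n_proteins: int = 400,
    p_both: float = 0.565,
    p_only_a: float = 0.394,
    p_exact_given_both: float = 0.808,
    p_relaxed_given_both: float = 0.942,
) -> Tuple[GOAnnotationMap, GOAnnotationMap, TruthRecord]:
    """Two protein→GO maps with a planted coverage partition and planted
    per-protein agreement outcomes (under the default relaxed criterion:
    3 levels, roots excluded).

    exact: both pipelines share a non-root term. relaxed-only: sibling terms
    under a shared non-root parent (agree within 3 levels, no shared term).
    disagree: terms from different namespaces, which share no ancestor at
    all. Truth holds the realized counts.
    """
    for name, p in [
        ("p_both", p_both),
        ("p_only_a", p_only_a),
        ("p_exact_given_both", p_exact_given_both),
        ("p_relaxed_given_both", p_relaxed_given_both),
    ]:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if p_both + p_only_a > 1.0 + 1e-12:
        raise ValueError("p_both + p_only_a must not exceed 1")
    if p_relaxed_given_both < p_exact_given_both:
        raise ValueError("p_relaxed_given_both must be >= p_exact_given_both")

    rng = random.Random(seed)
    roots = set(ontology.roots)
    non_root = sorted(t for t in ontology.terms if t not in roots)
    if not non_root:
        raise ValueError("ontology has no non-root terms")
    children_of: Dict[str, List[str]] = {}
    for tid, term in ontology.terms.items():
        for p in term.parents:
            children_of.setdefault(p, []).append(tid)
    sibling_pairs = sorted(
        (x, y)
        for parent, kids in children_of.items()
        if parent not in roots
        for x in kids
        for y in kids
        if x < y
    )
    if not sibling_pairs:
        raise ValueError(
            "ontology too shallow: no sibling pairs under a non-root parent"
        )
    by_namespace: Dict[str, List[str]] = {}
    for tid in non_root:
        by_namespace.setdefault(ontology.terms[tid].namespace, []).append(tid)
    namespaces = sorted(ns for ns, ts in by_namespace.items() if ts)
    if len(namespaces) < 2:
        raise ValueError("need terms in at least 2 namespaces to plant disagreement")

    a: Dict[str, Set[str]] = {}
    b: Dict[str, Set[str]] = {}
    counts = {"n_both": 0, "n_only_a": 0, "n_only_b": 0, "n_exact": 0, "n_relaxed": 0}
    for i in range(n_proteins):
        pid = f"P{i:05d}"
        u = rng.random()
        if u < p_both:
            counts["n_both"] += 1
            v = rng.random()
            if v < p_exact_given_both:
                t = rng.choice(non_root)
                a[pid], b[pid] = {t}, {t}
                counts["n_exact"] += 1
                counts["n_relaxed"] += 1
            elif v < p_relaxed_given_both:
                x, y = rng.choice(sibling_pairs)
                a[pid], b[pid] = {x}, {y}
                counts["n_relaxed"] += 1
            else:
                ns1, ns2 = rng.sample(namespaces, 2)
                a[pid] = {rng.choice(by_namespace[ns1])}
                b[pid] = {rng.choice(by_namespace[ns2])}
        elif u < p_both + p_only_a:
            counts["n_only_a"] += 1
            a[pid] = {rng.choice(non_root)}
        else:
            counts["n_only_b"] += 1
            b[pid] = {rng.choice(non_root)}

    n_union = counts["n_both"] + counts["n_only_a"] + counts["n_only_b"]
    values = dict(counts)
    values["n_union"] = n_union
    values["jaccard"] = counts["n_both"] / n_union if n_union else 0.0
    values["exact_rate"] = (
        counts["n_exact"] / counts["n_both"] if counts["n_both"] else 0.0
    )
    values["relaxed_rate"] = (
        counts["n_relaxed"] / counts["n_both"] if counts["n_both"] else 0.0
    )
    truth = TruthRecord(generator="go_maps", seed=seed, values=values)
    return (
        GOAnnotationMap(a, pipeline_label="pipeline_a"),
        GOAnnotationMap(b, pipeline_label="pipeline_b"),
        truth,
    )


def go_map_to_two_column(go_map: GOAnnotationMap) -> str:
    """Serialize a GO map in the two-column dialect parse_go_map reads."""
    lines = [
        f"{pid}\t{'|'.join(sorted(terms))}"
        for pid, terms in sorted(go_map.assignments.items())
    ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# tree pairs separated by a known number of NNI moves


def _random_binary_tree(rng: random.Random, n_leaves: int) -> PhyloTree:
    nodes = [TreeNode(label=f"S{i:03d}") for i in range(n_leaves)]
    for node in nodes:
        node.length = round(rng.uniform(0.01, 1.0), 4)
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        first = nodes.pop(i)
        j = rng.randrange(len(nodes))
        second = nodes.pop(j)
        parent = TreeNode(length=round(rng.uniform(0.01, 1.0), 4))
        parent.add_child(first)
        parent.add_child(second)
        nodes.append(parent)
    nodes[0].length = None
    return PhyloTree(nodes[0])


def _nni_candidates(tree: PhyloTree) -> List[TreeNode]:
    # internal nodes whose parent is internal and not the root
    return [
        node
        for node in tree.nodes()
        if not node.is_leaf
        and node.parent is not None
        and node.parent.parent is not None
    ]


def apply_nni(tree: PhyloTree, rng: random.Random) -> PhyloTree:
    """One random nearest-neighbour interchange; changes exactly one split."""
    candidates = _nni_candidates(tree)
    if not candidates:
        raise ValueError("tree too small for an NNI move")
    v = rng.choice(candidates)
    u = v.parent
    sibling = rng.choice([c for c in u.children if c is not v])
    child = rng.choice(v.children)
    u.children[u.children.index(sibling)] = child
    v.children[v.children.index(child)] = sibling
    child.parent, sibling.parent = u, v
    return PhyloTree(tree.root)


def make_tree_pair(
    seed: int, n_leaves: int = 200, n_nni_moves: int = 10
) -> Tuple[str, str, TruthRecord]:
    """Two newick trees where the second is the first after ``n_nni_moves``
    random NNI moves; their Robinson-Foulds distance is at most
    2·n_nni_moves (each move rewrites one internal split)."""
    if n_leaves < 5:
        raise ValueError("n_leaves must be >= 5")
    rng = random.Random(seed)
    tree1 = _random_binary_tree(rng, n_leaves)
    tree2 = PhyloTree(copy.deepcopy(tree1.root))
    for _ in range(n_nni_moves):
        tree2 = apply_nni(tree2, rng)
    truth = TruthRecord(
        generator="tree_pair",
        seed=seed,
        values={"n_leaves": n_leaves, "n_nni_moves": n_nni_moves,
                "rf_max": 2 * n_nni_moves},
    )
    return write_newick(tree1), write_newick(tree2), truth


# ---------------------------------------------------------------------------
# per-species tRNA prediction tables


_ISOTYPE_WEIGHTS = {
    "Ser": 6.7, "Ala": 6.2, "Gly": 5.9, "Arg": 5.7, "Leu": 5.6,
    "Lys": 4.7, "Val": 4.7, "Thr": 4.7, "Pro": 4.7, "Ile": 4.7,
    "Asp": 4.7, "Glu": 4.7, "Asn": 4.7, "Gln": 4.7, "His": 4.7,
    "Phe": 4.7, "Tyr": 4.7, "Cys": 4.7, "Trp": 4.7, "Met": 4.7,
}

_ANTICODONS = {iso: "NNN" for iso in _ISOTYPE_WEIGHTS}

_TRNA_HEADER = (
    "Sequence\t\ttRNA\tBounds\tBounds\ttRNA\tAnti\tIntron\tIntron\tInf\n"
    "Name    \ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore\tNote\n"
    "--------\t------\t-----\t----\t----\t-----\t-----\t---\t-----\t----\n"
)


def _quantile(sorted_values: List[float], q: float) -> float:
    # linear interpolation between order statistics, written out by hand so
    # the truth stays independent of the summary code it validates
    n = len(sorted_values)
    if n == 1:
        return float(sorted_values[0])
    pos = (n - 1) * q
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return sorted_values[lo] * (1 - frac) + sorted_values[hi] * frac


def make_trna_table(
    seed: int, n_species: int = 200
) -> Tuple[Dict[str, str], Dict[str, int], TruthRecord]:
    """Synthetic per-species tRNA prediction tables plus genome sizes.

    Species-level composition is drawn around the medians typical of insect
    genomes: ~3.6 confirmed tRNAs per Mbp on genomes with a median near
    135 Mbp (hence a median confirmed count near 489 and occupancy near
    0.027%), a wide pseudogene proportion centred near 20%, ~7% of confirmed
    tRNAs with introns, selenocysteine tRNAs in ~46% and suppressor tRNAs in
    ~42.5% of species, and isotype shares led by Ser/Ala/Gly/Arg/Leu. Truth
    holds the per-species confirmed counts and densities (cohort medians are
    recomputed with a local quantile routine).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = random.Random(seed)
    isotypes = list(_ISOTYPE_WEIGHTS)
    weights = list(_ISOTYPE_WEIGHTS.values())
    files: Dict[str, str] = {}
    genome_bp: Dict[str, int] = {}
    confirmed_counts: List[float] = []
    densities: List[float] = []
    values: Dict[str, object] = {"n_species": n_species}

    for i in range(n_species):
        species = f"Species_{i:03d}"
        size = int(135e6 * math.exp(rng.gauss(0.0, 0.8)))
        size = max(60_000_000, min(3_000_000_000, size))
        density = 3.63 * math.exp(rng.gauss(0.0, 0.77))
        n_confirmed = max(20, min(20000, round(density * size / 1e6)))
        p_pseudo = 1.0 / (1.0 + math.exp(-(rng.gauss(-1.402, 2.0))))
        n_pseudo = min(30000, round(n_confirmed * p_pseudo / (1.0 - p_pseudo + 1e-9)))
        intron_frac = min(0.3, 0.073 * math.exp(rng.gauss(0.0, 0.35)))

        rows: List[Tuple[str, int, int, str, str, int, int, float, str]] = []
        n_sec = rng.randint(1, 3) if rng.random() < 0.46 else 0
        n_sup = rng.randint(1, 2) if rng.random() < 0.425 else 0
        specials = ["SeC"] * n_sec + ["Sup"] * n_sup
        for k in range(n_confirmed):
            if k < len(specials):
                isotype = specials[k]
            else:
                isotype = rng.choices(isotypes, weights)[0]
            has_intron = rng.random() < intron_frac
            length = rng.randint(70, 90) + (rng.randint(10, 40) if has_intron else 0)
            begin = rng.randint(1, max(2, size - length - 1))
            end = begin + length - 1
            if rng.random() < 0.5:
                begin, end = end, begin  # reverse strand
            ib = min(begin, end) + 35 if has_intron else 0
            ie = ib + 12 if has_intron else 0
            score = round(rng.uniform(35.0, 95.0), 1)
            rows.append((f"scaffold_{k % 40 + 1}", begin, end,
                         isotype, _ANTICODONS.get(isotype, "NNN"),
                         ib, ie, score, ""))
        for _ in range(n_pseudo):
            isotype = rng.choices(isotypes, weights)[0]
            length = rng.randint(60, 85)
            begin = rng.randint(1, max(2, size - length - 1))
            end = begin + length - 1
            if rng.random() < 0.5:
                begin, end = end, begin
            score = round(rng.uniform(20.0, 40.0), 1)
            rows.append((f"scaffold_{rng.randint(1, 40)}", begin, end,
                         isotype, "NNN", 0, 0, score, "pseudo"))

        body = "".join(
            f"{name}\t{j + 1}\t{b}\t{e}\t{iso}\t{anti}\t{ib}\t{ie}\t{sc}\t{note}\n"
            for j, (name, b, e, iso, anti, ib, ie, sc, note) in enumerate(rows)
        )
        files[species] = _TRNA_HEADER + body
        genome_bp[species] = size
        confirmed_counts.append(float(n_confirmed))
        densities.append(n_confirmed / (size / 1e6))
        if n_species <= 20:
            values[f"{species}.confirmed_count"] = n_confirmed
            values[f"{species}.pseudo_count"] = n_pseudo
            values[f"{species}.genome_bp"] = size

    confirmed_counts.sort()
    densities.sort()
    values["median_confirmed"] = _quantile(confirmed_counts, 0.5)
    values["q1_confirmed"] = _quantile(confirmed_counts, 0.25)
    values["q3_confirmed"] = _quantile(confirmed_counts, 0.75)
    values["median_density_per_mbp"] = _quantile(densities, 0.5)
    truth = TruthRecord(generator="trna_table", seed=seed, values=values)
    return files, genome_bp, truth
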