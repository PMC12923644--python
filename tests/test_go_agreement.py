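"""GO coverage and agreement metrics, with an exhaustive relaxed-agreement
oracle built on networkx shortest paths."""

import networkx as nx
import pytest

from annotconcord import fixtures as fx
from annotconcord.formats_io import parse_obo
from annotconcord.go_agreement import (
    AgreementConfig,
    ancestors_within,
    coverage_jaccard,
    exact_agree,
    relaxed_agree,
    summarize_cohort,
    summarize_pair,
)
from annotconcord.model import GOAnnotationMap, Ontology


def gomap(d, label=""):
    return GOAnnotationMap({k: set(v) for k, v in d.items()}, label)


def relaxed_oracle(ontology, terms_a, terms_b, k, exclude_roots):
    """Triple loop over (a, b, candidate ancestor c) with networkx distances."""
    g = nx.DiGraph()
    g.add_nodes_from(ontology.terms)
    for tid, term in ontology.terms.items():
        for p in term.parents:
            g.add_edge(tid, p)
    for a in terms_a:
        if a not in ontology:
            continue
        da = nx.single_source_shortest_path_length(g, a)
        for b in terms_b:
            if b not in ontology:
                continue
            db = nx.single_source_shortest_path_length(g, b)
            for c in ontology.terms:
                if exclude_roots and c in ontology.roots:
                    continue
                if da.get(c, k + 1) <= k and db.get(c, k + 1) <= k:
                    return True
    return False


CHAIN = Ontology.from_edges({"C": {"B"}, "B": {"A"}})
DIAMOND = Ontology.from_edges({"D": {"B", "C"}, "B": {"A"}, "C": {"A"}})
SIBLINGS = Ontology.from_edges(
    {"parent": {"root"}, "x": {"parent"}, "y": {"parent"}}
)
ROOT_SIBLINGS = Ontology.from_edges({"x": {"root"}, "y": {"root"}})


class TestCoverage:
    def test_identical_key_sets(self):
        m = gomap({"p1": {"GO:0000001"}, "p2": {"GO:0000002"}})
        assert coverage_jaccard(m, m) == (2, 0, 0, 1.0)

    def test_disjoint_key_sets(self):
        a = gomap({"p1": {"GO:0000001"}})
        b = gomap({"p2": {"GO:0000001"}})
        assert coverage_jaccard(a, b) == (0, 1, 1, 0.0)

    def test_half_overlap(self):
        a = gomap({p: {"GO:0000001"} for p in ["p1", "p2", "p3"]})
        b = gomap({p: {"GO:0000001"} for p in ["p2", "p3", "p4"]})
        n_both, only_a, only_b, j = coverage_jaccard(a, b)
        assert (n_both, only_a, only_b) == (2, 1, 1)
        assert j == 0.5


class TestExact:
    def test_overlap_and_disjoint(self):
        assert exact_agree({"GO:1"}, {"GO:1", "GO:2"})
        assert not exact_agree({"GO:1"}, {"GO:2"})

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            exact_agree(set(), {"GO:1"})


class TestAncestors:
    def test_k0_is_the_term_itself(self):
        assert ancestors_within(CHAIN, "C", 0) == {"C": 0}

    def test_chain_distances(self):
        assert ancestors_within(CHAIN, "C", 2) == {"C": 0, "B": 1, "A": 2}

    def test_diamond_minimum_over_paths(self):
        assert ancestors_within(DIAMOND, "D", 2)["A"] == 2
        assert ancestors_within(DIAMOND, "D", 1) == {"D": 0, "B": 1, "C": 1}

    def test_unknown_term_rejected(self):
        with pytest.raises(KeyError):
            ancestors_within(CHAIN, "Z", 1)


class TestRelaxed:
    def test_identical_non_root_singletons_agree(self):
        assert relaxed_agree(CHAIN, {"C"}, {"C"})

    def test_siblings_under_non_root_parent_agree(self):
        assert relaxed_agree(SIBLINGS, {"x"}, {"y"})

    def test_root_ancestor_not_allowed(self):
        assert not relaxed_agree(ROOT_SIBLINGS, {"x"}, {"y"})
        assert relaxed_agree(
            ROOT_SIBLINGS, {"x"}, {"y"}, AgreementConfig(exclude_roots=False)
        )

    def test_unknown_terms_ignored_until_none_left(self):
        assert relaxed_agree(CHAIN, {"C", "GO:nope"}, {"C"})
        with pytest.raises(ValueError):
            relaxed_agree(CHAIN, {"GO:nope"}, {"C"})

    def test_k0_without_root_exclusion_equals_exact(self):
        config = AgreementConfig(max_levels=0, exclude_roots=False)
        cases = [({"x"}, {"y"}), ({"x"}, {"x"}), ({"x", "y"}, {"y"})]
        for ta, tb in cases:
            assert relaxed_agree(SIBLINGS, ta, tb, config) == exact_agree(ta, tb)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_oracle_on_random_dags(self, seed):
        import random

        obo, _ = fx.make_ontology(seed, n_terms=30, n_roots=3, edge_density=1.6)
        ont = parse_obo(obo)
        rng = random.Random(seed)
        terms = sorted(ont.terms)
        for _ in range(15):
            ta = set(rng.sample(terms, rng.randint(1, 5)))
            tb = set(rng.sample(terms, rng.randint(1, 5)))
            for k in (0, 1, 3):
                for exclude in (True, False):
                    config = AgreementConfig(max_levels=k, exclude_roots=exclude)
                    assert relaxed_agree(ont, ta, tb, config) == relaxed_oracle(
                        ont, ta, tb, k, exclude
                    ), (ta, tb, k, exclude)

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_in_k_and_superset_of_exact(self, seed):
        import random

        obo, _ = fx.make_ontology(seed + 50, n_terms=25, n_roots=2)
        ont = parse_obo(obo)
        rng = random.Random(seed)
        terms = sorted(t for t in ont.terms if t not in ont.roots)
        for _ in range(10):
            ta = set(rng.sample(terms, rng.randint(1, 4)))
            tb = set(rng.sample(terms, rng.randint(1, 4)))
            previous = False
            for k in range(0, 5):
                current = relaxed_agree(ont, ta, tb, AgreementConfig(max_levels=k))
                assert current or not previous  # once true, stays true
                previous = current
            if exact_agree(ta, tb):  # shared non-root term implies relaxed
                assert relaxed_agree(ont, ta, tb)

    def test_cross_namespace_terms_never_agree_when_roots_excluded(self):
        obo, _ = fx.make_ontology(7, n_terms=20, n_roots=2)
        ont = parse_obo(obo)
        by_ns = {}
        for tid, term in ont.terms.items():
            if tid not in ont.roots:
                by_ns.setdefault(term.namespace, []).append(tid)
        ns1, ns2 = sorted(by_ns)[:2]
        for a in by_ns[ns1]:
            for b in by_ns[ns2]:
                assert not relaxed_agree(ont, {a}, {b})


class TestSummaries:
    def test_identical_maps_are_fully_concordant(self):
        m = gomap({"p1": {"C"}, "p2": {"B"}})
        summary = summarize_pair(CHAIN, m, m)
        assert summary.jaccard == summary.exact_rate == 1.0
        assert summary.relaxed_rate == 1.0  # C and B are non-root

    def test_no_shared_proteins_reports_zero_rates(self):
        a = gomap({"p1": {"C"}})
        b = gomap({"p2": {"C"}})
        summary = summarize_pair(CHAIN, a, b)
        assert summary.n_both == 0
        assert summary.exact_rate == summary.relaxed_rate == 0.0

    def test_planted_rates_reproduced(self):
        obo, _ = fx.make_ontology(5, n_terms=40)
        ont = parse_obo(obo)
        map_a, map_b, truth = fx.make_go_maps(5, ont, n_proteins=250)
        summary = summarize_pair(ont, map_a, map_b)
        assert summary.n_both == truth.values["n_both"]
        assert summary.exact_rate == pytest.approx(truth.values["exact_rate"])
        assert summary.relaxed_rate == pytest.approx(truth.values["relaxed_rate"])
        assert summary.jaccard == pytest.approx(truth.values["jaccard"])

    def test_single_species_cohort_median_is_that_species(self):
        m = gomap({"p1": {"C"}})
        summary = summarize_cohort([("sp1", m, m)], CHAIN)
        med, q1, q3 = summary.cohort["jaccard"]
        assert med == q1 == q3 == 1.0

    def test_cohort_median_of_three(self):
        obo, _ = fx.make_ontology(5, n_terms=40)
        ont = parse_obo(obo)
        pairs = []
        for i, p_both in enumerate([0.2, 0.5, 0.8]):
            a, b, _ = fx.make_go_maps(
                i, ont, n_proteins=400, p_both=p_both, p_only_a=(1 - p_both) / 2
            )
            pairs.append((f"sp{i}", a, b))
        summary = summarize_cohort(pairs, ont)
        med, _, _ = summary.cohort["jaccard"]
        assert med == pytest.approx(summary.per_species["jaccard"][1])

    def test_pooled_equals_concatenated_maps(self):
        obo, _ = fx.make_ontology(11, n_terms=40)
        ont = parse_obo(obo)
        pairs = []
        cat_a, cat_b = {}, {}
        for i in range(4):
            a, b, _ = fx.make_go_maps(100 + i, ont, n_proteins=120)
            pairs.append((f"sp{i}", a, b))
            cat_a.update({f"sp{i}:{p}": t for p, t in a.assignments.items()})
            cat_b.update({f"sp{i}:{p}": t for p, t in b.assignments.items()})
        summary = summarize_cohort(pairs, ont)
        pooled = summarize_pair(ont, gomap(cat_a), gomap(cat_b))
        assert summary.jaccard == pytest.approx(pooled.jaccard)
        assert summary.exact_rate == pytest.approx(pooled.exact_rate)

    def test_coverage_percentages_from_proteome_sizes(self):
        a = gomap({"p1": {"C"}, "p2": {"C"}})
        b = gomap({"p1": {"C"}})
        summary = summarize_cohort(
            [("sp1", a, b)], CHAIN, n_proteins={"sp1": 4}
        )
        row = summary.per_species.iloc[0]
        assert row["coverage_a_pct"] == 50.0
        assert row["coverage_b_pct"] == 25.0
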