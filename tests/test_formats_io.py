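"""Parsing and writing of the external formats."""

import io

import pandas as pd
import pytest

from annotconcord import fixtures as fx
from annotconcord.formats_io import (
    count_fasta_records,
    decorate_terms,
    fasta_lengths,
    parse_gff3,
    parse_go_map,
    parse_gtf,
    parse_newick,
    parse_obo,
    parse_trnascan,
    write_newick,
    write_tsv_report,
)
from annotconcord.model import ParseError
from annotconcord.structure_eval import collect_units

GTF_ONE = 'chr1\tsrc\tCDS\t11\t40\t.\t+\t0\tgene_id "g1"; transcript_id "t1";\n'

GFF3_MINI = """\
chr1\tsrc\tgene\t11\t40\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t11\t40\t.\t+\t.\tID=t1;Parent=g1;Ontology_term=GO:0008150,GO:0003674
chr1\tsrc\tCDS\t11\t40\t.\t+\t0\tParent=t1
"""

OBO_MINI = """\
format-version: 1.2

[Term]
id: GO:0000001
name: rootA
namespace: biological_process

[Term]
id: GO:0000002
name: termB
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: gone
is_obsolete: true
"""


class TestGtf:
    def test_single_cds_row(self):
        annot = parse_gtf(GTF_ONE)
        assert annot.n_genes == 1 and annot.n_transcripts == 1
        (tx,) = list(annot.transcripts())
        assert [(iv.start, iv.end) for iv in tx.intervals] == [(11, 40)]

    def test_empty_stream(self):
        assert parse_gtf("").n_genes == 0

    def test_other_feature_types_and_comments_ignored(self):
        text = "# comment\n" + GTF_ONE.replace("CDS", "exon") + GTF_ONE
        assert parse_gtf(text, feature_kind="CDS").n_transcripts == 1

    @pytest.mark.parametrize(
        "mutation, fragment",
        [
            (lambda s: s.replace('gene_id "g1"; ', ""), "gene_id"),
            (lambda s: s.replace("11\t40", "40\t11"), "start"),
            (lambda s: s.replace("\t+\t", "\t.\t"), "unstranded"),
        ],
    )
    def test_malformed_rows_raise_with_line_number(self, mutation, fragment):
        with pytest.raises(ParseError, match="line 1"):
            parse_gtf(mutation(GTF_ONE))

    def test_fixture_counts_match_independent_line_scan(self):
        ref, _, _ = fx.make_annotation_pair(seed=7)
        annot = parse_gtf(ref)
        genes, txs = set(), set()
        for line in ref.splitlines():
            attrs = line.split("\t")[8]
            genes.add(attrs.split('gene_id "')[1].split('"')[0])
            txs.add(attrs.split('transcript_id "')[1].split('"')[0])
        assert annot.n_genes == len(genes)
        assert annot.n_transcripts == len(txs)


class TestGff3:
    def test_minimal_gene_mrna_cds(self):
        annot, go_map = parse_gff3(GFF3_MINI)
        assert annot.n_genes == 1 and annot.n_transcripts == 1
        assert go_map.assignments == {"t1": {"GO:0008150", "GO:0003674"}}

    def test_two_transcripts_share_gene(self):
        text = GFF3_MINI + (
            "chr1\tsrc\tmRNA\t11\t60\t.\t+\t.\tID=t2;Parent=g1\n"
            "chr1\tsrc\tCDS\t11\t60\t.\t+\t0\tParent=t2\n"
        )
        annot, _ = parse_gff3(text)
        assert len(annot.genes["g1"]) == 2

    def test_undefined_parent_rejected(self):
        bad = GFF3_MINI.replace("Parent=g1", "Parent=gX")
        with pytest.raises(ParseError, match="gX"):
            parse_gff3(bad)

    def test_cyclic_parent_chain_rejected(self):
        text = (
            "chr1\tsrc\tgene\t1\t90\t.\t+\t.\tID=g1;Parent=t1\n"
            "chr1\tsrc\tmRNA\t1\t90\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\tsrc\tCDS\t1\t90\t.\t+\t0\tParent=t1\n"
        )
        with pytest.raises(ParseError, match="cyclic"):
            parse_gff3(text)

    def test_gtf_and_gff3_encodings_agree_on_units(self):
        gtf = (
            'chr1\ts\tCDS\t1\t50\t.\t+\t0\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\ts\tCDS\t100\t150\t.\t+\t0\tgene_id "g1"; transcript_id "t1";\n'
        )
        gff3 = (
            "chr1\ts\tgene\t1\t150\t.\t+\t.\tID=g1\n"
            "chr1\ts\tmRNA\t1\t150\t.\t+\t.\tID=t1;Parent=g1\n"
            "chr1\ts\tCDS\t1\t50\t.\t+\t0\tParent=t1\n"
            "chr1\ts\tCDS\t100\t150\t.\t+\t0\tParent=t1\n"
        )
        a = parse_gtf(gtf)
        b, _ = parse_gff3(gff3)
        for level in ("exon", "transcript"):
            assert collect_units(a, level) == collect_units(b, level)


class TestNewick:
    def test_two_leaf_lengths(self):
        tree = parse_newick("(A:1,B:2);")
        lengths = {leaf.label: leaf.length for leaf in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 2.0}
        assert len(tree.root.children) == 2

    def test_absent_lengths_stay_absent(self):
        tree = parse_newick("((A,B),C);")
        assert all(leaf.length is None for leaf in tree.leaves())

    @pytest.mark.parametrize("bad", ["", "((A,B);", "(A,A);"])
    def test_bad_newick_rejected(self, bad):
        with pytest.raises(ParseError):
            parse_newick(bad)

    def test_round_trip_preserves_topology_labels_lengths(self):
        nwk, _ = fx.make_taxonomy_tree(seed=1, n_leaves=10)
        once = parse_newick(nwk)
        twice = parse_newick(write_newick(once))

        def canonical(node):
            if node.is_leaf:
                return (node.label, node.length)
            children = sorted((canonical(c) for c in node.children), key=repr)
            return (tuple(children), node.length)

        assert canonical(once.root) == canonical(twice.root)


class TestObo:
    def test_roots_parents_and_obsolete_skip(self):
        ont = parse_obo(OBO_MINI)
        assert ont.roots == {"GO:0000001"}
        assert ont.parents("GO:0000002") == {"GO:0000001"}
        assert "GO:0000003" not in ont
        assert ont.terms["GO:0000002"].namespace == "BP"

    def test_dangling_is_a_rejected(self):
        bad = OBO_MINI.replace("is_a: GO:0000001", "is_a: GO:9999999")
        with pytest.raises(ParseError, match="GO:9999999"):
            parse_obo(bad)

    def test_fixture_edges_match_truth(self):
        obo, truth = fx.make_ontology(seed=3)
        ont = parse_obo(obo)
        edges = sorted(
            f"{child}>{p}" for child, t in ont.terms.items() for p in t.parents
        )
        assert ";".join(edges) == truth.values["edges"]
        assert ";".join(sorted(ont.roots)) == truth.values["roots"]

    def test_part_of_only_with_flag(self):
        text = OBO_MINI.replace(
            "is_a: GO:0000001", "relationship: part_of GO:0000001"
        )
        assert parse_obo(text).parents("GO:0000002") == frozenset()
        assert parse_obo(text, include_part_of=True).parents("GO:0000002") == {
            "GO:0000001"
        }


class TestGoMap:
    def test_two_column(self):
        go = parse_go_map("p1\tGO:0000001|GO:0000002")
        assert go.assignments == {"p1": {"GO:0000001", "GO:0000002"}}

    def test_interproscan_rows_union_without_duplicates(self):
        def row(go_field):
            cols = ["p1", "md5", "100", "Pfam", "PF1", "d", "1", "99", "1e-5",
                    "T", "01-01-2020", "IPR1", "desc", go_field]
            return "\t".join(cols)

        text = "\n".join(
            [row("GO:0000001(InterPro)|GO:0000002"), row("GO:0000002"), row("-")]
        )
        go = parse_go_map(text, dialect="interproscan_tsv")
        assert go.assignments == {"p1": {"GO:0000001", "GO:0000002"}}

    def test_invalid_tokens_warn_and_are_counted(self):
        with pytest.warns(UserWarning, match="2 malformed"):
            go = parse_go_map("p1\tGO:1|GO:0000002|banana")
        assert go.assignments == {"p1": {"GO:0000002"}}
        assert go.n_invalid_tokens == 2

    def test_fixture_maps_round_trip_through_two_column(self):
        obo, _ = fx.make_ontology(seed=5)
        ont = parse_obo(obo)
        map_a, _, _ = fx.make_go_maps(seed=5, ontology=ont, n_proteins=50)
        text = fx.go_map_to_two_column(map_a)
        assert parse_go_map(text).assignments == map_a.assignments


class TestTrnascan:
    TABLE = (
        "Sequence\t\ttRNA\tBounds\nName\ttRNA #\tBegin\tEnd\n--------\t---\n"
        "scaf1\t1\t100\t172\tSer\tAGA\t0\t0\t66.6\n"
        "scaf1\t2\t500\t420\tAla\tAGC\t530\t545\t50.1\n"
        "scaf1\t3\t900\t970\tLys\tCTT\t0\t0\t28.0\tpseudo\n"
    )

    def test_fields_flags_and_intron_counts(self):
        records = parse_trnascan(self.TABLE, species="sp1")
        assert len(records) == 3
        assert [r.intron_count for r in records] == [0, 1, 0]
        assert [r.is_pseudo for r in records] == [False, False, True]
        assert records[1].begin == 500 and records[1].end == 420  # reverse strand
        assert records[0].score == 66.6

    def test_short_row_rejected_with_line_number(self):
        with pytest.raises(ParseError, match="line 4"):
            parse_trnascan(self.TABLE.replace("\t66.6", ""))


class TestDecorateAndReports:
    def test_decorate_known_and_unknown_terms(self):
        ont = parse_obo(OBO_MINI)
        from annotconcord.model import GOAnnotationMap

        go = GOAnnotationMap({"p2": {"GO:0000002"}, "p1": {"GO:0000001", "GO:1111111"}})
        table = decorate_terms(ont, go)
        assert list(table["protein_id"]) == ["p1", "p1", "p2"]
        assert list(table["namespace"]) == ["BP", "other", "BP"]
        assert table.loc[1, "term_name"] == "unknown"

    def test_decorate_empty_map(self):
        from annotconcord.model import GOAnnotationMap

        assert decorate_terms(parse_obo(OBO_MINI), GOAnnotationMap({})).empty

    def test_tsv_round_trip(self, tmp_path):
        table = pd.DataFrame({"a": [1, 2], "b": ["x", "y"]})
        out = tmp_path / "report.tsv"
        write_tsv_report(table, out)
        assert out.read_text().count("\n") == 3
        back = pd.read_csv(out, sep="\t")
        pd.testing.assert_frame_equal(table, back)

    def test_header_only_for_empty_table(self, tmp_path):
        out = tmp_path / "empty.tsv"
        write_tsv_report(pd.DataFrame(columns=["a", "b"]), out)
        assert out.read_text() == "a\tb\n"


class TestFasta:
    FAA = ">p1 desc\nMKV\nLL\n>p2\nMACDEFGHIK\n"

    def test_count_and_lengths(self):
        assert count_fasta_records(io.StringIO(self.FAA)) == 2
        assert list(fasta_lengths(io.StringIO(self.FAA))) == [5, 10]
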