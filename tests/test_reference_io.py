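"""Reference dump parsing, indexing and caching."""

from __future__ import annotations

import io

import pytest

from taxonmap.reference_io import (
    ConfigurationError,
    DialectError,
    Reference,
    StructuralError,
    TaxonNode,
    build_indexes,
    load_reference_set,
    parse_reference,
    read_cache,
    write_cache,
)

TAXDUMP_NODES = (
    "1\t|\t1\t|\tno rank\t|\n"
    "2\t|\t1\t|\tgenus\t|\n"
    "3\t|\t2\t|\tspecies\t|\n"
)
TAXDUMP_NAMES = (
    "1\t|\troot\t|\t\t|\tscientific name\t|\n"
    "2\t|\tRubia\t|\t\t|\tscientific name\t|\n"
    "3\t|\tRubia cordifolia\t|\t\t|\tscientific name\t|\n"
    "3\t|\tRubia sylvatica\t|\t\t|\tsynonym\t|\n"
    "3\t|\tmadder\t|\t\t|\tcommon name\t|\n"
)

DWC_HEADER = ("taxonID\tscientificName\ttaxonRank\tparentNameUsageID\t"
              "acceptedNameUsageID\ttaxonomicStatus\n")


class TestNcbiTaxdump:
    def test_three_line_fixture(self):
        result = parse_reference(
            "ncbi-taxdump",
            {"names": io.StringIO(TAXDUMP_NAMES),
             "nodes": io.StringIO(TAXDUMP_NODES)},
        )
        assert len(result) == 3
        species = result["3"]
        assert species.canonical_name == "Rubia cordifolia"
        assert species.synonyms == ["Rubia sylvatica"]  # common name ignored
        assert species.lineage == ["1", "2"]  # root, genus
        assert species.lineage_ranks == ["no rank", "genus"]
        assert result["1"].parent_id == ""  # self-parent root normalized

    def test_requires_both_streams(self):
        with pytest.raises(DialectError):
            parse_reference("ncbi-taxdump", {"names": io.StringIO("")})

    def test_cycle_detected(self):
        nodes = "1\t|\t2\t|\tgenus\t|\n2\t|\t1\t|\tgenus\t|\n"
        names = ("1\t|\tAlpha\t|\t\t|\tscientific name\t|\n"
                 "2\t|\tBeta\t|\t\t|\tscientific name\t|\n")
        with pytest.raises(StructuralError, match="cyclic"):
            parse_reference("ncbi-taxdump",
                            {"names": io.StringIO(names),
                             "nodes": io.StringIO(nodes)})


class TestDwcTaxon:
    def test_empty_table_with_header(self):
        result = parse_reference("dwc-taxon", io.StringIO(DWC_HEADER))
        assert len(result) == 0

    def test_synonym_attaches_to_accepted_target(self):
        table = (DWC_HEADER
                 + "A\tRubia cordifolia\tspecies\t\t\taccepted\n"
                 + "B\tRubia sylvatica\tspecies\t\tA\tsynonym\n")
        result = parse_reference("dwc-taxon", io.StringIO(table))
        assert list(result) == ["A"]
        assert result["A"].synonyms == ["Rubia sylvatica"]

    def test_orphan_synonym_dropped_and_counted(self):
        table = (DWC_HEADER
                 + "A\tRubia cordifolia\tspecies\t\t\taccepted\n"
                 + "B\tRubia sylvatica\tspecies\t\tZZZ\tsynonym\n")
        result = parse_reference("dwc-taxon", io.StringIO(table))
        assert len(result) == 1
        assert result.dropped == 1

    def test_doubtful_retained_flagged(self):
        table = DWC_HEADER + "A\tRubia dubia\tspecies\t\t\tdoubtful\n"
        result = parse_reference("dwc-taxon", io.StringIO(table))
        assert result["A"].status == "doubtful"

    def test_missing_column_named(self):
        bad = "taxonID\tscientificName\ttaxonRank\n" "A\tRubia\tgenus\n"
        with pytest.raises(DialectError, match="parentNameUsageID"):
            parse_reference("dwc-taxon", io.StringIO(bad))

    def test_authority_stripped_at_parse_time(self):
        table = (DWC_HEADER
                 + "A\tPanax ginseng C.A.Mey.\tspecies\t\t\taccepted\n")
        result = parse_reference("dwc-taxon", io.StringIO(table))
        assert result["A"].canonical_name == "Panax ginseng"


class TestIndexes:
    def test_basic_and_synonym_indexing(self):
        nodes = {
            "X": TaxonNode("X", "Rubia cordifolia", "species",
                           synonyms=["Panax schinseng"]),
        }
        name_index, genus_index = build_indexes(nodes)
        assert genus_index["rubia"] == ["X"]
        assert name_index["rubia cordifolia"] == [("X", False)]
        assert name_index["panax schinseng"] == [("X", True)]
        assert genus_index["panax"] == ["X"]

    def test_shared_first_block(self):
        nodes = {
            "1": TaxonNode("1", "Agathis", "genus"),
            "2": TaxonNode("2", "Agathis", "genus"),
        }
        _, genus_index = build_indexes(nodes)
        assert genus_index["agathis"] == ["1", "2"]

    def test_completeness(self, gen_world):
        for ref in gen_world["refset"]:
            for node in ref.nodes.values():
                for name in [node.canonical_name] + node.synonyms:
                    entries = ref.name_index[name.casefold()]
                    assert node.taxon_id in {t for t, _ in entries}
                    first = name.split()[0].casefold()
                    assert node.taxon_id in ref.genus_index[first]

    def test_lineage_matches_parent_chain(self, gen_world):
        """Brute-force oracle: lineage equals repeated parent_id lookup."""
        for ref in gen_world["refset"]:
            for node in ref.nodes.values():
                chain = []
                cur = node.parent_id
                while cur:
                    chain.append(cur)
                    cur = ref.nodes[cur].parent_id
                assert node.lineage == list(reversed(chain))
                assert len(node.lineage) == len(node.lineage_ranks)
                assert node.taxon_id not in node.lineage


class TestReferenceSet:
    def test_pooled_valid_names_is_union(self, tiny_refset):
        expected = set()
        for ref in tiny_refset:
            for node in ref.nodes.values():
                expected.add(node.canonical_name.casefold())
                expected.update(s.casefold() for s in node.synonyms)
        assert tiny_refset.valid_names == expected

    def test_duplicate_name_rejected(self, ncbi_ref):
        from taxonmap.reference_io import ReferenceSet

        rs = ReferenceSet()
        rs.add(ncbi_ref)
        with pytest.raises(ConfigurationError):
            rs.add(Reference.from_nodes("ncbi", {}))

    def test_missing_file_is_configuration_error(self, tmp_path):
        with pytest.raises(ConfigurationError, match="missing file"):
            load_reference_set(
                [("x", "dwc-taxon", tmp_path / "nope.tsv")]
            )

    def test_empty_config_rejected(self):
        with pytest.raises(ConfigurationError):
            load_reference_set([])

    def test_load_from_files(self, tmp_path, gen_world):
        truths = gen_world["truths"]
        refset = load_reference_set([
            ("ncbi", "ncbi-taxdump", dict(truths["ncbi"].paths)),
            ("col", "dwc-taxon", truths["col"].paths["taxon"]),
        ])
        assert len(refset) == 2
        assert len(refset["ncbi"].nodes) == len(truths["ncbi"].nodes)


class TestCache:
    def test_round_trip(self, tmp_path, gen_world):
        ref = gen_world["refset"]["ncbi"]
        write_cache(ref, tmp_path)
        loaded = read_cache("ncbi", tmp_path)
        assert loaded.nodes.keys() == ref.nodes.keys()
        for tid, node in ref.nodes.items():
            other = loaded.nodes[tid]
            assert (node.canonical_name, node.rank, node.parent_id,
                    node.lineage, node.lineage_ranks, node.synonyms,
                    node.status) == (
                other.canonical_name, other.rank, other.parent_id,
                other.lineage, other.lineage_ranks, other.synonyms,
                other.status)
        assert loaded.name_index == ref.name_index
        assert loaded.genus_index == ref.genus_index
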