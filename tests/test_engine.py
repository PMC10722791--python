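"""The mapping cascade: exact, recursive, nearest, corrections, flags,
partial mapping, and full map_name behaviour."""

from __future__ import annotations

import pytest

from taxonmap import codes
from taxonmap.codes import ALL_CODES, MULTI_MATCH_CODES, NO_TAXON_CODES
from taxonmap.engine import (
    candidate_pool,
    correct_epithet,
    correct_whole,
    exact_match,
    map_name,
    nearest_taxon,
    partial_map,
    recursive_match,
    strain_nearest,
    top_lineage_label,
)
from taxonmap.preprocess import make_query
from taxonmap.reference_io import Reference, ReferenceSet, TaxonNode
from conftest import make_nodes


class TestExactMatch:
    def test_raw_canonical(self, ncbi_ref):
        hit = exact_match(make_query("Actinidia deliciosa"), ncbi_ref)
        assert hit.status_code == codes.EXACT_RAW_CANONICAL
        assert hit.taxon_ids == ("11",)

    def test_case_insensitive(self, ncbi_ref):
        hit = exact_match(make_query("actinidia deliciosa"), ncbi_ref)
        assert hit.status_code == codes.EXACT_CASEFOLD_CANONICAL
        assert hit.taxon_ids == ("11",)

    def test_synonym(self, ncbi_ref):
        hit = exact_match(make_query("Rubia sylvatica"), ncbi_ref)
        assert hit.status_code == codes.EXACT_RAW_SYNONYM
        assert hit.taxon_ids == ("21",)  # resolved to the accepted taxon

    def test_simple_corrected(self, ncbi_ref):
        hit = exact_match(make_query("Rubia cordifolia L."), ncbi_ref)
        assert hit.status_code == codes.EXACT_CORRECTED_CANONICAL

    def test_no_hit(self, ncbi_ref):
        assert exact_match(make_query("Nonexistens nomen"), ncbi_ref) is None


class TestRecursiveMatch:
    def test_synonym_recursion_unique(self, tiny_refset):
        rec = map_name("Actinidia chinensis deliciosa", tiny_refset, "ncbi")
        assert rec.status_code == codes.RECURSIVE_UNIQUE
        assert rec.taxon_ids == ("11",)

    def test_multiple_distinct_targets(self):
        # two sources whose synonyms point at two different target taxa
        target = Reference.from_nodes("t", make_nodes(
            TaxonNode("1", "root", "no rank", ""),
            TaxonNode("2", "Plantae", "kingdom", "1"),
            TaxonNode("3", "Alpha beta", "species", "2"),
            TaxonNode("4", "Gamma delta", "species", "2"),
        ))
        src = Reference.from_nodes("s", make_nodes(
            TaxonNode("s1", "root", "no rank", ""),
            TaxonNode("s2", "Plantae", "kingdom", "s1"),
            TaxonNode("s3", "Epsilon zeta", "species", "s2",
                      synonyms=["Alpha beta"]),
            TaxonNode("s4", "Epsilon zeta", "species", "s2",
                      synonyms=["Gamma delta"]),
        ))
        sources = [(src, src.nodes["s3"]), (src, src.nodes["s4"])]
        out = recursive_match(sources, target)
        assert out.status_code == codes.RECURSIVE_MULTIPLE
        assert out.taxon_ids == ("3", "4")

    def test_no_match_elsewhere(self, tiny_refset):
        rec = map_name("Nonexistens nomen", tiny_refset, "ncbi")
        assert rec.status_code == codes.UNMAPPED


class TestNearestTaxon:
    def test_genus_level(self, tiny_refset, ncbi_ref, col_ref):
        # Rubia tinctorum exists only in col; ncbi has the genus
        sources = [(col_ref, col_ref.nodes["c22"])]
        out = nearest_taxon(sources, ncbi_ref)
        assert out.taxon_ids == ("20",)
        assert out.status_code == codes.NEAREST_BASE + 1  # genus tier

    def test_hemihomonym_domain_agreement(self, ncbi_ref, col_ref):
        # "Agathis ovata" is a plant in col; ncbi holds both a plant and an
        # animal genus named Agathis — the plant genus must win.
        sources = [(col_ref, col_ref.nodes["c31"])]
        out = nearest_taxon(sources, ncbi_ref)
        assert out.taxon_ids == ("30",)
        assert top_lineage_label(ncbi_ref, ncbi_ref.nodes["30"]) == "plantae"
        # and the animal species picks the wasp genus
        sources = [(col_ref, col_ref.nodes["c41"])]
        out = nearest_taxon(sources, ncbi_ref)
        assert out.taxon_ids == ("31",)

    def test_kingdom_level_fallback(self, ncbi_ref):
        src = Reference.from_nodes("s", make_nodes(
            TaxonNode("s1", "root", "no rank", ""),
            TaxonNode("s2", "Plantae", "kingdom", "s1"),
            TaxonNode("s3", "Ignotum", "genus", "s2"),
            TaxonNode("s4", "Ignotum arcanum", "species", "s3"),
        ))
        out = nearest_taxon([(src, src.nodes["s4"])], ncbi_ref)
        assert out.taxon_ids == ("2",)  # Plantae
        assert out.status_code == codes.NEAREST_BASE + 6  # kingdom tier


class TestCandidatePool:
    def test_same_first_block(self, col_ref):
        # all three congeners pass the length filter; the character-profile
        # filter then keeps only the compositionally similar one
        query = "Rubia cordifolai"
        congeners = ["Rubia cordifolia", "Rubia tinctorum", "Rubia peregrina"]
        assert all(abs(len(n) - len(query)) <= 3 for n in congeners)
        pool = candidate_pool(query, col_ref, max_d=3)
        names = {n for n, _, _ in pool}
        assert "Rubia cordifolia" in names
        assert names <= set(congeners)

    def test_length_bound_excludes(self, col_ref):
        pool = candidate_pool("Rubia cordifoliaaaaaaaaaaa", col_ref, max_d=3)
        assert all(abs(len(n) - 26) <= 3 for n, _, _ in pool)

    def test_empty_bucket(self, col_ref):
        assert candidate_pool("Zyzzyva sp", col_ref, max_d=3) == []


class TestCorrectEpithet:
    def test_single_typo(self, col_ref):
        out = correct_epithet(make_query("Rubia cordifolai"), col_ref)
        assert out.taxon_ids == ("c21",)
        assert out.distance == 1
        assert out.status_code == codes.EPITHET_CANONICAL_UNIQUE

    def test_tie_reports_all(self):
        ref = Reference.from_nodes("t", make_nodes(
            TaxonNode("1", "root", "no rank", ""),
            TaxonNode("2", "Rubia", "genus", "1"),
            TaxonNode("3", "Rubia corda", "species", "2"),
            TaxonNode("4", "Rubia cordu", "species", "2"),
        ))
        out = correct_epithet(make_query("Rubia corde"), ref)
        assert out.status_code == codes.EPITHET_CANONICAL_MULTIPLE
        assert out.taxon_ids == ("3", "4")
        assert out.distance == 1

    def test_threshold(self, col_ref):
        out = correct_epithet(make_query("Rubia zzzzzzzzzzz"), col_ref)
        assert out is None


class TestCorrectWhole:
    def test_declension_exact(self, tiny_refset, ncbi_ref):
        out = correct_whole(make_query("Glycyrrhizae radix"), tiny_refset,
                            ncbi_ref)
        assert out.status_code == codes.DECLENSION_UNIQUE
        assert out.taxon_ids == ("60",)

    def test_declension_multiple(self, tiny_refset):
        ref = Reference.from_nodes("t", make_nodes(
            TaxonNode("1", "root", "no rank", ""),
            TaxonNode("2", "Glycyrrhiza", "genus", "1"),
            TaxonNode("3", "Glycyrrhize", "genus", "1"),
        ))
        rs = ReferenceSet()
        rs.add(ref)
        out = correct_whole(make_query("Glycyrrhizae radix"), rs, ref)
        assert out.status_code == codes.DECLENSION_MULTIPLE
        assert out.taxon_ids == ("2", "3")

    def test_whole_string_distance(self, tiny_refset, ncbi_ref):
        # typo in the first word-block: the genus bucket misses, the whole
        # correction still recovers the name
        out = correct_whole(make_query("Actinidia delicoisa"), tiny_refset,
                            ncbi_ref)
        assert out.taxon_ids == ("11",)
        assert out.status_code == codes.WHOLE_CANONICAL_UNIQUE

    def test_garbage_falls_through(self, tiny_refset, ncbi_ref):
        assert correct_whole(make_query("qqqq zzzz"), tiny_refset,
                             ncbi_ref) is None


class TestFlaggedNearest:
    def test_strain_to_genus(self, tiny_refset, ncbi_ref):
        out = strain_nearest(make_query("Streptomyces sp. ABC-123"),
                             tiny_refset, ncbi_ref)
        assert out.status_code == codes.STRAIN_NEAREST
        assert out.taxon_ids == ("40",)

    def test_strain_to_species_container(self, tiny_refset, ncbi_ref):
        out = strain_nearest(make_query("Bacillus subtilis KCTC-3135"),
                             tiny_refset, ncbi_ref)
        assert out.status_code == codes.STRAIN_NEAREST
        assert out.taxon_ids == ("51",)

    def test_confer_returns_higher_taxon(self, tiny_refset, ncbi_ref):
        out = strain_nearest(make_query("Rubia cf. cordifolia"),
                             tiny_refset, ncbi_ref)
        assert out.status_code == codes.CONFER_NEAREST
        assert out.taxon_ids == ("20",)  # parent genus of the species match

    def test_affinis_with_year(self, tiny_refset, ncbi_ref):
        out = strain_nearest(make_query("Bacillus aff. subtilis 1997"),
                             tiny_refset, ncbi_ref)
        assert out.status_code == codes.AFFINIS_NEAREST
        assert out.taxon_ids == ("50",)  # parent of Bacillus subtilis


class TestPartialMap:
    def test_genus_prefix(self, tiny_refset, ncbi_ref):
        out = partial_map(make_query("Rubia totallywrongword"), tiny_refset,
                          ncbi_ref)
        assert out.status_code == codes.PARTIAL
        assert out.taxon_ids == ("20",)

    def test_two_block_prefix(self, tiny_refset, ncbi_ref):
        out = partial_map(
            make_query("Rubia cordifolia extraneous trailing words"),
            tiny_refset, ncbi_ref)
        assert out.taxon_ids == ("21",)

    def test_unmappable(self, tiny_refset, ncbi_ref):
        assert partial_map(make_query("xyzzy"), tiny_refset, ncbi_ref) is None


class TestMapName:
    def test_exact_path(self, tiny_refset):
        rec = map_name("Actinidia deliciosa", tiny_refset, "ncbi")
        assert rec.status_code == 0
        assert rec.others["col"].taxon_ids == ("c11",)  # via synonym there

    def test_dropout_has_no_taxon(self, tiny_refset):
        rec = map_name("Tobacco mosaic virus", tiny_refset, "ncbi")
        assert rec.status_code in range(90, 100)
        assert rec.taxon_ids == ()

    def test_hybrid_dropout(self, tiny_refset):
        rec = map_name("Mentha × piperita", tiny_refset, "ncbi")
        assert rec.status_code == codes.DROPOUT_HYBRID

    def test_vernacular_substitution(self, tiny_refset):
        rec = map_name("kiwifruit", tiny_refset, "ncbi",
                       vmap={"kiwifruit": "Actinidia deliciosa"})
        assert rec.taxon_ids == ("11",)
        assert rec.query.vernacular_applied

    def test_unknown_target_raises(self, tiny_refset):
        with pytest.raises(KeyError):
            map_name("Rubia", tiny_refset, "nope")

    @pytest.mark.parametrize("raw", [
        "Actinidia deliciosa", "Rubia cordifolai", "Glycyrrhizae radix",
        "Streptomyces sp. ABC-123", "Tobacco mosaic virus", "xyzzy", "   x",
        "Mentha × piperita", "(only parenthetical)", "Rubia cf. cordifolia",
    ])
    def test_totality_and_code_table(self, tiny_refset, raw):
        """Every input yields exactly one status code from the declared
        table, and taxon ids are empty exactly for the no-taxon codes."""
        rec = map_name(raw, tiny_refset, "ncbi")
        assert rec.status_code in ALL_CODES
        assert (rec.taxon_ids == ()) == (rec.status_code in NO_TAXON_CODES)
        if len(rec.taxon_ids) > 1:
            assert rec.status_code in MULTI_MATCH_CODES

    def test_cascade_soundness_on_generated_world(self, gen_world):
        """A raw canonical name of the target maps to exactly that taxon
        with status 0 — no correction stage may fire on valid names."""
        refset = gen_world["refset"]
        ref = refset["ncbi"]
        species = [n for n in ref.nodes.values() if n.rank == "species"]
        for node in species[:60]:
            rec = map_name(node.canonical_name, refset, "ncbi",
                           include_others=False)
            assert rec.status_code == 0
            assert rec.taxon_ids == (node.taxon_id,)

    def test_synonyms_map_to_accepted(self, gen_world):
        refset = gen_world["refset"]
        ref = refset["ncbi"]
        for node in ref.nodes.values():
            for syn in node.synonyms[:1]:
                rec = map_name(syn, refset, "ncbi", include_others=False)
                assert rec.status_code == codes.EXACT_RAW_SYNONYM
                assert rec.taxon_ids == (node.taxon_id,)
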