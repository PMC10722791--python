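"""Shared fixtures: a small hand-built two-reference world plus a generated
synthetic reference set."""

from __future__ import annotations

import pytest

from taxonmap.reference_io import (
    Reference,
    ReferenceSet,
    TaxonNode,
    _materialize_lineages,
)
from taxonmap.synthetic import FixtureSpec, generate_reference_set


def make_nodes(*nodes: TaxonNode) -> dict[str, TaxonNode]:
    d = {n.taxon_id: n for n in nodes}
    _materialize_lineages(d)
    return d


def _ncbi_like() -> dict[str, TaxonNode]:
    return make_nodes(
        TaxonNode("1", "root", "no rank", ""),
        TaxonNode("2", "Plantae", "kingdom", "1"),
        TaxonNode("3", "Animalia", "kingdom", "1"),
        TaxonNode("4", "Bacteria", "kingdom", "1"),
        TaxonNode("10", "Actinidia", "genus", "2"),
        TaxonNode("11", "Actinidia deliciosa", "species", "10"),
        TaxonNode("20", "Rubia", "genus", "2"),
        TaxonNode("21", "Rubia cordifolia", "species", "20",
                  synonyms=["Rubia sylvatica"]),
        # hemihomonym: a conifer genus and a braconid-wasp genus
        TaxonNode("30", "Agathis", "genus", "2"),
        TaxonNode("31", "Agathis", "genus", "3"),
        TaxonNode("40", "Streptomyces", "genus", "4"),
        TaxonNode("50", "Bacillus", "genus", "4"),
        TaxonNode("51", "Bacillus subtilis", "species", "50"),
        TaxonNode("60", "Glycyrrhiza", "genus", "2"),
    )


def _col_like() -> dict[str, TaxonNode]:
    return make_nodes(
        TaxonNode("c1", "root", "no rank", ""),
        TaxonNode("c2", "Plantae", "kingdom", "c1"),
        TaxonNode("c3", "Animalia", "kingdom", "c1"),
        TaxonNode("c10", "Actinidia", "genus", "c2"),
        TaxonNode("c11", "Actinidia chinensis deliciosa", "species", "c10",
                  synonyms=["Actinidia deliciosa"]),
        TaxonNode("c20", "Rubia", "genus", "c2"),
        TaxonNode("c21", "Rubia cordifolia", "species", "c20"),
        TaxonNode("c22", "Rubia tinctorum", "species", "c20"),
        TaxonNode("c23", "Rubia peregrina", "species", "c20"),
        TaxonNode("c30", "Agathis", "genus", "c2"),
        TaxonNode("c31", "Agathis ovata", "species", "c30"),
        TaxonNode("c40", "Agathis", "genus", "c3"),
        TaxonNode("c41", "Agathis tibialis", "species", "c40"),
    )


@pytest.fixture()
def ncbi_ref() -> Reference:
    return Reference.from_nodes("ncbi", _ncbi_like())


@pytest.fixture()
def col_ref() -> Reference:
    return Reference.from_nodes("col", _col_like())


@pytest.fixture()
def tiny_refset(ncbi_ref, col_ref) -> ReferenceSet:
    rs = ReferenceSet()
    rs.add(ncbi_ref)
    rs.add(col_ref)
    return rs


DIALECTS = {"ncbi": "ncbi-taxdump", "col": "dwc-taxon"}


@pytest.fixture(scope="session")
def gen_world(tmp_path_factory):
    """Two generated references (120 species, 6 hemihomonym genus pairs)
    sharing half their species, parsed back through reference_io."""
    from taxonmap.reference_io import parse_reference

    outdir = tmp_path_factory.mktemp("gen_world")
    spec = FixtureSpec(n_species=120, n_genera=30, hemihomonym_pairs=6,
                       synonym_rate=0.3, shared_fraction=0.5, seed=42)
    truths, master = generate_reference_set(spec, DIALECTS, outdir)
    refset = ReferenceSet()
    for name, truth in truths.items():
        parsed = parse_reference(DIALECTS[name], truth.paths)
        refset.add(Reference.from_nodes(name, parsed.nodes, parsed.dropped))
    return {"spec": spec, "truths": truths, "master": master,
            "refset": refset}
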