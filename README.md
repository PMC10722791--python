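# taxonmap

High-throughput resolution of scientific-name strings to taxon identifiers
in a chosen taxonomic reference (NCBI taxonomy, Catalogue of Life, EoL,
GBIF, or any Darwin-Core-style checklist), consulting several references at
once.

## The problem

Scientific names are poor database identifiers: the accepted ("canonical")
name of a species differs between checklists (kiwifruit is *Actinidia
chinensis deliciosa* in CoL but *Actinidia deliciosa* in NCBI taxonomy),
names drift over time, identical names are applied to taxa in different
kingdoms (hemihomonyms, e.g. *Agathis* the conifer vs. *Agathis* the
braconid wasp), and real-world sources — especially natural-product and
ethnobotanical databases — are full of typos, strain codes, authority
strings, Latin-genitive drug names (*Glycyrrhizae radix*) and vernaculars.
`taxonmap` normalizes such inputs and maps each one to the best taxon in a
target reference, using every loaded reference as a source of synonymy and
phylogenetic lineage.

## The mapping cascade

Each query runs through an ordered cascade; the producing stage determines
a numeric status code:

| stage | codes | behaviour |
|---|---|---|
| exact match | 0–5 | raw / simple-corrected / case-insensitive hit in the target |
| synonym recursion | 6, 8 | names matched in *other* references probe the target through their canonical names and synonyms |
| nearest taxon | 10–18 | the matched entity's lineage is walked tip→root; the lowest-rank ancestor resolvable in the target wins, disambiguating homonymic genera by agreement of the top-rank (domain/kingdom) lineage label |
| flagged nearest | 40–49 | strain-coded, `cf.`/`aff.` and `<Genus> sp.` inputs bypass edit-distance correction and map to their containing taxon |
| dropout | 90–99 | virus/phytoplasma/… and hybrid queries carry no taxonomic signal of their own |
| epithet correction | 20–24 | Damerau–Levenshtein distance (insertions, deletions, substitutions, adjacent transpositions; threshold `max_d = 3`) within the same-first-word-block candidate pool |
| whole-input correction | 30–36 | Latin-declension candidate expansion, then whole-string distance with length/character pruning |
| partial mapping | 100 / 1000 | longest word-block prefix that matches exactly; 1000 = unmapped |

A name that is valid in at least one reference is never edit-distance
corrected — synonymy and lineage are consulted first.

## Worked example

```python
from taxonmap import map_name
from taxonmap.reference_io import Reference, ReferenceSet, TaxonNode, _materialize_lineages

def ref(name, *nodes):
    d = {n.taxon_id: n for n in nodes}
    _materialize_lineages(d)
    return Reference.from_nodes(name, d)

refset = ReferenceSet()
refset.add(ref("ncbi",
    TaxonNode("1", "root", "no rank", ""),
    TaxonNode("2", "Plantae", "kingdom", "1"),
    TaxonNode("3", "Actinidia", "genus", "2"),
    TaxonNode("4", "Actinidia deliciosa", "species", "3"),
    TaxonNode("5", "Glycyrrhiza", "genus", "2"),
))
refset.add(ref("col",
    TaxonNode("c1", "root", "no rank", ""),
    TaxonNode("c2", "Plantae", "kingdom", "c1"),
    TaxonNode("c3", "Actinidia", "genus", "c2"),
    TaxonNode("c4", "Actinidia chinensis deliciosa", "species", "c3",
              synonyms=["Actinidia deliciosa"]),
))

for raw in ["Actinidia deliciosa", "Actinidia chinensis deliciosa",
            "Actinidia delicoisa", "Glycyrrhizae radix",
            "Tobacco mosaic virus"]:
    rec = map_name(raw, refset, "ncbi")
    print(f"{raw!r:40} status={rec.status_code:<4} ids={rec.taxon_ids} "
          f"match={rec.matched_name!r} stage={rec.stage}")
```

prints

```
'Actinidia deliciosa'                    status=0    ids=('4',) match='Actinidia deliciosa' stage=exact
'Actinidia chinensis deliciosa'          status=6    ids=('4',) match='Actinidia deliciosa' stage=recursive
'Actinidia delicoisa'                    status=20   ids=('4',) match='Actinidia deliciosa' stage=epithet-correction
'Glycyrrhizae radix'                     status=30   ids=('5',) match='Glycyrrhiza' stage=declension
'Tobacco mosaic virus'                   status=90   ids=() match='' stage=dropout
```

Reading the output: the verbatim canonical name maps exactly (status 0);
the CoL-only name reaches the NCBI-style entry through CoL's synonym link
(status 6); a one-letter typo is repaired within the *Actinidia* candidate
pool at edit distance 1 (status 20); the Latin-genitive drug name is
reduced to its nominative genus (status 30); and a virus name, which names
the host rather than the query's own taxon, is dropped with no identifier
(status 90).

## Command line

```bash
taxonmap fixtures --out-dir refs/ncbi --n-species 100 --n-genera 20   # synthetic reference
taxonmap init --ref-dir refs          # build _node_dict/_genus_dict caches
taxonmap map --ref-dir refs --input names.txt --target ncbi --out-dir result
taxonmap diag --ref-dir refs --out-dir reports     # discrepancy analytics
taxonmap npmerge --ref-dir refs --target ncbi --pairs a.tsv --pairs b.tsv
```

`map` writes one tab-separated result file per input file
(`taxonmap_result_[date]_[time]_[input].txt`), including the best match in
every other loaded reference next to the target result.

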