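# Methods

This note documents the models, rules, and numerical choices behind
`taxonmap`, what the synthetic study sets do and do not emulate, and the
design decisions taken where more than one reasonable option existed.

## Reference model

Every reference — whether parsed from an NCBI-style taxdump
(`names.dmp`/`nodes.dmp`) or a Darwin-Core-style taxon table — is reduced
to the same node model: a reference-local identifier, a canonical
scientific name, a rank label, a parent pointer, the materialized ancestor
lineage (root→parent) with aligned rank labels, a synonym list, and an
accepted/doubtful status. Synonym rows are attached to their accepted
target at parse time; synonym rows whose target is missing are dropped and
counted rather than invented. Name matching is case-insensitive
throughout: indexes are keyed on case-folded strings while nodes keep the
original casing. Authority text embedded in reference name columns is
stripped with the same rule used for queries, so indexes hold bare
binomials.

Darwin-Core parsing expects the fixed column core `{taxonID,
scientificName, taxonRank, parentNameUsageID, acceptedNameUsageID,
taxonomicStatus}` (the common denominator of the CoL, EoL and GBIF
exports); extra columns are ignored and there is no `meta.xml`-driven
column discovery. Rows whose status is `doubtful` are retained but
flagged; statuses containing "synonym", and `misapplied`, attach to their
accepted target. Parent pointers that cannot be resolved truncate the
lineage at that point rather than failing the whole parse; cyclic parent
chains are a structural error naming a cycle member.

## Query normalization

`simple_correct` removes parenthesized spans, collapses punctuation and
whitespace, and strips trailing authorship. The authority rule is: drop
trailing tokens that are connectives (`&`, `et`, `ex`, …), single-letter
abbreviations with a period ("L."), or uppercase-initial purely alphabetic
tokens past the second word-block; trailing four-digit description years
(1700–2099) adjacent to these are dropped too. The first two word-blocks
are never removed (except the single-letter abbreviation case, which can
never be a valid epithet), so binomials survive normalization. The
function is idempotent, which the test suite asserts by property.

Semantic screening is a pure function of the normalized string. A token
containing digits that is not a plausible description year marks the query
`strain_like`; `cf.`/`aff.` mark uncertainty; `×`, an isolated infix `x`,
or the word "hybrid" mark hybrids; the keywords `virus`, `viroid`,
`phytoplasma`, `endosymbiont`, `phage` (config-extensible) mark dropouts —
such queries usually carry the *host's* name and convey no taxonomic
information about themselves; single-block queries and `<Genus> sp.` forms
are `genus_only`.

Latin-declension handling removes materia-medica part terms (`herba`,
`radix`, `cortex`, `folium`, `flos`, `fructus`, `semen`, `rhizoma`, plus
the conjunction `et`; config-extensible) and expands each remaining block
through a suffix table of standard Latin noun declensions
(`-ae→{-a,-e}`, `-i→{-us,-um,-is}`, `-is→{-is,-e,-s}`, `-orum→{-um,-us}`,
`-arum→{-a}`, `-us→{-us}`), combining the per-block candidate sets as a
Cartesian product. The part-term-stripped original is always among the
candidates. The table is a declared design choice: it covers the common
first/second/third-declension genitives seen in traditional-medicine drug
names but makes no claim of covering every Latin inflection.

## Distance primitive

Edit distance is the restricted Damerau–Levenshtein (optimal string
alignment) form: insertions, deletions, substitutions and adjacent
transpositions each cost one, and a transposed pair is not edited further.
The implementation is the standard three-row dynamic program with an
optional cap that abandons a candidate as soon as every cell of the
current row exceeds the threshold. The test suite checks it exhaustively
against an independent implementation of the recursive definition for all
`acgt` string pairs of combined length ≤ 6, plus thousands of seeded
longer pairs, and asserts symmetry/identity properties.

Both correction stages use `max_d = 3`: typographic errors beyond three
edits are rare, and a larger radius mostly manufactures false matches
between legitimate congeners. Candidate pruning before any distance is
computed: same first word-block (epithet stage only), length difference
≤ `max_d`, and character-multiset difference ≤ `2·max_d` (each edit
changes the character profile by at most two).

## Cascade order and status codes

Stages run in the order: exact match in the target; synonym recursion via
other references; lineage-nearest mapping; dropout; flagged-name nearest
mapping; epithet correction; whole-input correction (declension first);
partial prefix mapping. Flag priority is dropout > hybrid > cf./aff. >
strain > genus-only. Two deliberate properties follow: a name valid in
*any* loaded reference is never edit-distance corrected, and
strain-coded / cf. / aff. inputs skip the correction stages entirely
(strain codes are alphanumeric noise under edit distance).

The code *ranges* per stage (0–5, 6/8, 10–18, 20–24, 30–36, 40–49, 90–99,
100, 1000) are structural; the per-code table inside each range is this
package's own declaration (see `taxonmap.codes`): e.g. 0/1 raw
canonical/synonym, 2/3 after simple correction, 4/5 case-insensitive,
nearest codes are 10 + rank tier (species, genus, family, order, class,
phylum, kingdom, domain, other), 40 strain, 41/42 cf./aff., 43 genus
placeholder, and within correction ranges unique/multiple and
canonical/synonym outcomes are distinguished. Multi-taxon results are
reported (sorted by identifier) rather than silently choosing one; codes
that may carry several identifiers are declared in
`taxonmap.codes.MULTI_MATCH_CODES`.

Rank tiers order "lowest taxonomic rank" for nearest mapping: species and
everything below it share tier 0, then genus, family, order, class,
phylum, kingdom, domain. Sub-/super-/infra- forms share their base rank's
tier; unranked lineage members inherit the tier of the nearest ranked
descendant during the walk.

Hemihomonym disambiguation: when a lineage probe (typically a genus name)
hits several target taxa, the taxon whose top-rank lineage label
(domain/kingdom tier, compared case-folded by name) agrees with the source
lineage is preferred; remaining ties break to the smallest identifier.
This is what keeps a plant query from landing on an identically named
wasp genus.

cf./aff. inputs return a *higher* taxon of the residual match (the parent
of a species-level hit), reflecting the meaning of the abbreviation: the
material is near, but not confirmed to be, the named species.

Open choices resolved here: whole-input correction searches canonical
names and synonyms (consistent with the pooled valid-name list);
declension candidates that are valid only in a non-target reference are
resolved into the target through synonym recursion and then lineage-nearest
mapping; `sp.`-bearing queries skip epithet correction and route to
genus-level nearest mapping.

## Synthetic study sets

The generator builds a single-root taxonomy (root → kingdom → family →
genus → species) with pronounceable consonant–vowel names. Species-level
names (canonicals and synonyms) are kept at pairwise edit distance
≥ `2·max_d + 1 = 7`, which makes recovery from ≤ 3 injected typos
unambiguous by the triangle inequality; genus and family names are kept
unique and well separated at their shorter lengths. An optional
near-duplicate rate plants sibling species within 1–2 edits of an existing
name, deliberately breaking the guarantee to exercise multi-match
behaviour; 1% is used in the near-duplicate study as a realistic density
of confusable congener pairs. The typo injector draws operations uniformly
from {substitution, insertion, deletion, adjacent transposition} at
uniform positions, preserves the first character by default (so the
first-word-block pruning stage stays exercised; a switch disables this),
and verifies the resulting distance never exceeds the requested magnitude.

Multi-reference sets share a configurable fraction of species (default
50%) and partition the rest, so every reference holds names absent from
the others — the raw material for recursion and nearest-mapping studies.
Planted hemihomonym pairs are twin genera bearing one name under two
different kingdoms.

What the fixtures do *not* emulate: real nomenclatural authorship strings,
rank-heterogeneous checklist quirks (incertae sedis placements, chained
synonymy), the heavy-tailed genus sizes of real taxonomies, and real
vernacular vocabularies. Passing the suites therefore demonstrates the
algorithmic contracts (recovery, routing, conservation), not
corpus-level accuracy on any particular public checklist, whose values
are version-dependent.

The occurrence-pair generator plans a support histogram first and then
realizes it: each planned pair is a distinct (species, structure-string)
combination placed into exactly `support` source tables, with the species
name optionally re-spelled per source as a typo, a Latin-genitive form, a
strain-suffixed form, or a registered vernacular. Structure
canonicalization is an injected dependency (identity in tests; an
RDKit-backed canonical-SMILES normalizer is provided for real use);
normalizer failures exclude the pair and are counted, never fatal.
Integration keeps pairs that map to a *unique* taxon at species rank or
below; genus-level, ambiguous and unmapped names are excluded and tallied
so that input rows = merged rows + exclusions exactly.

## Study sizes

The acceptance script uses a two-reference world of 600 species in 120
genera with 25 hemihomonym pairs (typo studies over all 450 species of the
target reference per error magnitude), a 500-species single-reference
world for the near-duplicate study, 30 constructed synonym-recursion
cases, 150-name strain and declension studies, and a 75-pair occurrence
plan across four sources with 10 planned exclusions. The in-suite studies
use a 500-species world. These sizes sit in the regime where every
expected value is exact by construction while the whole suite stays
interactive.

## Known limitations

* The per-code semantics within each status range are a declared stand-in,
  not a reverse-engineered copy of any particular tool's table.
* The authority-stripping heuristic can truncate names whose epithets are
  (incorrectly) capitalized in the source, and does not parse authorship
  into structured author/year records.
* The declension table handles the common genitive suffixes only; Greek
  third-declension stems and irregular nouns are out of scope.
* No phonetic matching and no machine-learned candidate ranking; the
  distance primitive is deliberately the classic one.
* Reconciliation of conflicting references into a merged taxonomy is a
  non-goal: each reference stays independent, and cross-reference
  disagreement is reported, not resolved.
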