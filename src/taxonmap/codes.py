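"""Mapping status codes and taxonomic rank tiers.

The cascade assigns every query exactly one status code per target
reference. Codes are grouped in ranges by producing stage:

====== =======================================================
0-5    exact match in the target reference
6, 8   recursive synonym match via another reference
10-18  nearest-taxon (lineage) mapping, keyed to the rank tier
20-24  edit-distance correction of the specific epithet
30-36  whole-input correction (Latin declension, then edit distance)
40-49  nearest mapping for strain-coded / cf. / aff. / genus-only names
90-99  rule-based dropout (no taxonomic signal in the query)
100    partial (prefix) mapping
1000   unmapped
====== =======================================================

The per-code semantics inside each range are this package's own declared
table (documented in docs/methods.md); only the range boundaries are fixed
by the mapping workflow itself.
"""

from __future__ import annotations

# -- exact matching (target reference) ---------------------------------------
EXACT_RAW_CANONICAL = 0        # input string is a canonical name, verbatim
EXACT_RAW_SYNONYM = 1          # input string is a synonym, verbatim
EXACT_CORRECTED_CANONICAL = 2  # canonical after simple correction
EXACT_CORRECTED_SYNONYM = 3    # synonym after simple correction
EXACT_CASEFOLD_CANONICAL = 4   # canonical via case-insensitive match
EXACT_CASEFOLD_SYNONYM = 5     # synonym via case-insensitive match

# -- recursive synonym matching via other references -------------------------
RECURSIVE_UNIQUE = 6
RECURSIVE_MULTIPLE = 8

# -- nearest-taxon mapping: 10 + rank tier ------------------------------------
NEAREST_BASE = 10

# -- epithet-level edit-distance correction -----------------------------------
EPITHET_CANONICAL_UNIQUE = 20
EPITHET_CANONICAL_MULTIPLE = 21
EPITHET_SYNONYM_UNIQUE = 22
EPITHET_SYNONYM_MULTIPLE = 23
EPITHET_MIXED_MULTIPLE = 24

# -- whole-input correction ----------------------------------------------------
DECLENSION_UNIQUE = 30
DECLENSION_MULTIPLE = 31
WHOLE_CANONICAL_UNIQUE = 32
WHOLE_CANONICAL_MULTIPLE = 33
WHOLE_SYNONYM_UNIQUE = 34
WHOLE_SYNONYM_MULTIPLE = 35
WHOLE_MIXED_MULTIPLE = 36

# -- flagged-name nearest mapping ----------------------------------------------
STRAIN_NEAREST = 40     # strain-coded name -> containing species/genus
CONFER_NEAREST = 41     # cf.: higher taxon of the referenced match
AFFINIS_NEAREST = 42    # aff.: higher taxon of the referenced match
GENUS_PLACEHOLDER = 43  # "<Genus> sp." / bare generic epithet

# -- dropout -------------------------------------------------------------------
DROPOUT_BASE = 90  # 90 + keyword index (see dropout_code)
DROPOUT_HYBRID = 95
DROPOUT_OTHER = 98
DROPOUT_CONTENT_FREE = 99

PARTIAL = 100
UNMAPPED = 1000

#: Codes that never carry a taxon id.
NO_TAXON_CODES = frozenset(range(90, 100)) | {UNMAPPED}

#: Codes under which a record may carry several taxon ids. Exact codes are
#: included because a reference may itself contain homonymous entries.
MULTI_MATCH_CODES = frozenset(
    {0, 1, 2, 3, 4, 5, RECURSIVE_MULTIPLE,
     EPITHET_CANONICAL_MULTIPLE, EPITHET_SYNONYM_MULTIPLE, EPITHET_MIXED_MULTIPLE,
     DECLENSION_MULTIPLE, WHOLE_CANONICAL_MULTIPLE, WHOLE_SYNONYM_MULTIPLE,
     WHOLE_MIXED_MULTIPLE, PARTIAL}
)

#: Every status code the engine can emit.
ALL_CODES = frozenset(
    list(range(0, 6)) + [6, 8] + list(range(10, 19)) + list(range(20, 25))
    + list(range(30, 37)) + list(range(40, 50)) + list(range(90, 100))
    + [PARTIAL, UNMAPPED]
)

_DROPOUT_ORDER = ("virus", "viroid", "phytoplasma", "endosymbiont", "phage")


def dropout_code(keyword: str) -> int:
    """Status code for a dropout keyword (stable across configs)."""
    if keyword == "hybrid":
        return DROPOUT_HYBRID
    if keyword == "content-free":
        return DROPOUT_CONTENT_FREE
    try:
        return DROPOUT_BASE + _DROPOUT_ORDER.index(keyword)
    except ValueError:
        return DROPOUT_OTHER


# -- rank tiers ----------------------------------------------------------------
# Tier 0 is the lowest (species and below); nearest-mapping codes are
# 10 + tier. Ranks between the named tiers (sub-/super-/infra- forms) share
# the tier of their base rank; unranked lineage members inherit the tier of
# the nearest ranked descendant during lineage walks.

SPECIES_TIER = 0

_BASE_TIERS = {
    "species": 0,
    "genus": 1,
    "family": 2,
    "order": 3,
    "class": 4,
    "phylum": 5,
    "division": 5,
    "kingdom": 6,
    "superkingdom": 7,
    "domain": 7,
    "realm": 7,
}

_SPECIES_LEVEL = {
    "subspecies", "variety", "varietas", "subvariety", "forma", "form",
    "forma specialis", "strain", "isolate", "serotype", "serovar",
    "biotype", "genotype", "morph", "pathogroup",
}

_GENUS_LEVEL = {"subgenus", "section", "subsection", "series", "subseries",
                "species group", "species subgroup"}

_FAMILY_LEVEL = {"tribe", "subtribe"}

MAX_TIER = 8  # "no rank" / unknown placed above every named tier


def rank_tier(rank: str) -> int | None:
    """Map a rank label to its tier, or ``None`` if unranked/unknown."""
    r = rank.strip().casefold()
    if not r or r == "no rank" or r == "clade" or r == "unranked":
        return None
    if r in _BASE_TIERS:
        return _BASE_TIERS[r]
    if r in _SPECIES_LEVEL:
        return 0
    if r in _GENUS_LEVEL:
        return 1
    if r in _FAMILY_LEVEL:
        return 2
    if r == "superkingdom":  # handled above; kept before prefix stripping
        return 7
    for prefix in ("super", "sub", "infra", "parv"):
        if r.startswith(prefix) and r[len(prefix):] in _BASE_TIERS:
            return _BASE_TIERS[r[len(prefix):]]
    return None


def nearest_code(tier: int) -> int:
    """Status code for a nearest-taxon hit at the given rank tier."""
    return NEAREST_BASE + min(tier, MAX_TIER)
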