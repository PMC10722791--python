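"""Integration of species–compound occurrence tables.

Natural-product occurrence databases record (species name, compound) pairs
with heterogeneous name spellings and structure encodings. This module maps
each name to the target taxonomic reference, canonicalizes the structure
string through an injected normalizer, and merges duplicates across source
databases — the number of sources independently reporting a pair becomes
its degree of support.

Only pairs whose name maps to a *unique* taxon at species level or better
enter the unified set; everything else is excluded and counted, so that
``input pairs == merged occurrences + excluded`` always holds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .codes import NO_TAXON_CODES, SPECIES_TIER, rank_tier
from .config import DEFAULT_CONFIG, MapperConfig
from .engine import map_name
from .reference_io import ReferenceSet

__all__ = [
    "SpeciesCompoundPair",
    "IntegrationResult",
    "identity_normalizer",
    "rdkit_normalizer",
    "read_pair_table",
    "integrate_pairs",
    "support_histogram",
    "write_unified",
]


def identity_normalizer(structure: str) -> str:
    """Pass-through structure normalizer (strings compared verbatim)."""
    s = structure.strip()
    if not s:
        raise ValueError("empty structure")
    return s


def rdkit_normalizer(structure: str) -> str:
    """Canonical-SMILES normalizer backed by RDKit, when it is installed.

    Raises ``ValueError`` for unparsable structures (the pair is then
    excluded and counted, not fatal).
    """
    from rdkit import Chem  # deferred; RDKit is an optional dependency

    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparsable structure: {structure!r}")
    return Chem.MolToSmiles(mol)


@dataclass
class SpeciesCompoundPair:
    """One unified occurrence: a taxon, a canonical structure, its sources."""

    taxon_id: str
    structure: str
    sources: set[str] = field(default_factory=set)
    source_names: set[str] = field(default_factory=set)
    n_rows: int = 0  # input rows merged into this pair

    @property
    def support(self) -> int:
        return len(self.sources)


@dataclass
class IntegrationResult:
    """Unified pair set plus the exclusion ledger."""

    pairs: dict[tuple[str, str], SpeciesCompoundPair]
    excluded: dict[str, int]
    input_count: int

    @property
    def excluded_total(self) -> int:
        return sum(self.excluded.values())

    @property
    def merged_rows(self) -> int:
        """Input rows that reached the unified set; with the exclusions this
        conserves the input count exactly."""
        return sum(p.n_rows for p in self.pairs.values())


def read_pair_table(path: str | Path) -> list[tuple[str, str]]:
    """Read a per-source TSV of (name, structure); extra columns ignored."""
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return rows
        for rec in reader:
            if len(rec) >= 2 and rec[0].strip():
                rows.append((rec[0].strip(), rec[1].strip()))
    return rows


def _species_level_unique(record) -> bool:
    """Unique single-taxon mapping at species rank tier or below."""
    if record.status_code in NO_TAXON_CODES or len(record.taxon_ids) != 1:
        return False
    tier = rank_tier(record.matched_rank)
    return tier is not None and tier <= SPECIES_TIER


def integrate_pairs(
    pair_tables: Mapping[str, Sequence[tuple[str, str]] | str | Path],
    refset: ReferenceSet,
    target: str,
    structure_normalizer: Callable[[str], str] = identity_normalizer,
    vmap: Mapping[str, str] | None = None,
    config: MapperConfig = DEFAULT_CONFIG,
) -> IntegrationResult:
    """Map, standardize and merge per-source pair tables.

    ``pair_tables`` maps a source label to rows or a TSV path. Name→taxon
    mapping results are cached per unique raw name, so large tables with
    recurring species are cheap. Exclusions are tallied by reason:
    ``unmapped`` (no taxon), ``not_species_level`` (resolved above species
    rank), ``multiple_taxa`` (ambiguous), ``structure_error``.
    """
    excluded = {"unmapped": 0, "not_species_level": 0,
                "multiple_taxa": 0, "structure_error": 0}
    name_cache: dict[str, tuple[str | None, str]] = {}
    pairs: dict[tuple[str, str], SpeciesCompoundPair] = {}
    input_count = 0

    def resolve(name: str) -> tuple[str | None, str]:
        """(taxon_id or None, exclusion reason)."""
        if name in name_cache:
            return name_cache[name]
        record = map_name(name, refset, target, config=config, vmap=vmap,
                          include_others=False)
        if record.status_code in NO_TAXON_CODES:
            out = (None, "unmapped")
        elif len(record.taxon_ids) != 1:
            out = (None, "multiple_taxa")
        elif not _species_level_unique(record):
            out = (None, "not_species_level")
        else:
            out = (record.taxon_ids[0], "")
        name_cache[name] = out
        return out

    for source in sorted(pair_tables):
        rows = pair_tables[source]
        if isinstance(rows, (str, Path)):
            rows = read_pair_table(rows)
        for name, structure in rows:
            input_count += 1
            taxon_id, reason = resolve(name)
            if taxon_id is None:
                excluded[reason] += 1
                continue
            try:
                canon = structure_normalizer(structure)
            except ValueError:
                excluded["structure_error"] += 1
                continue
            key = (taxon_id, canon)
            pair = pairs.get(key)
            if pair is None:
                pair = pairs[key] = SpeciesCompoundPair(taxon_id, canon)
            pair.sources.add(source)
            pair.source_names.add(name)
            pair.n_rows += 1

    return IntegrationResult(pairs=pairs, excluded=excluded,
                             input_count=input_count)


def support_histogram(result: IntegrationResult) -> dict[int, int]:
    """Counts of unified pairs by degree of support; sums to the number of
    unique pairs."""
    hist: dict[int, int] = {}
    for pair in result.pairs.values():
        hist[pair.support] = hist.get(pair.support, 0) + 1
    return dict(sorted(hist.items()))


def write_unified(
    result: IntegrationResult, path: str | Path
) -> Path:
    """Write the unified pair table (taxon, structure, sources, support)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("taxon_id\tstructure\tsources\tsupport\n")
        for key in sorted(result.pairs):
            p = result.pairs[key]
            fh.write(f"{p.taxon_id}\t{p.structure}\t"
                     f"{','.join(sorted(p.sources))}\t{p.support}\n")
    return path
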