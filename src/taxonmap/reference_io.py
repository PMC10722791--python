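"""Parsing taxonomic reference dumps into a unified node model.

Two dialects are supported:

* ``ncbi-taxdump`` — the NCBI taxonomy distribution (``names.dmp`` +
  ``nodes.dmp``, fields separated by ``\\t|\\t`` and records terminated by
  ``\\t|``);
* ``dwc-taxon`` — Darwin-Core-style taxon tables (tab-separated with a
  header), the common core of CoL ``Taxon.tsv``, EoL ``taxon.tab`` and the
  GBIF backbone ``Taxon.tsv``.

Synonym rows are attached to their accepted target; lineages are
materialized by walking parent links; name and genus (first word-block)
indexes are built case-folded with original casing preserved on the nodes.
Authority text embedded in name columns is stripped with the same rule the
query preprocessor uses, so the indexes store bare binomials.
"""

from __future__ import annotations

import csv
import gzip
import io
import urllib.request
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .config import DEFAULT_CONFIG, MapperConfig
from .preprocess import ContentFreeInputError, simple_correct

__all__ = [
    "TaxonNode",
    "Reference",
    "ReferenceSet",
    "ParseResult",
    "DialectError",
    "StructuralError",
    "ConfigurationError",
    "parse_reference",
    "build_indexes",
    "load_reference_set",
    "write_cache",
    "read_cache",
    "REFERENCE_URLS",
    "download_reference",
]


class DialectError(ValueError):
    """Input files do not match the declared dialect."""


class StructuralError(ValueError):
    """The reference graph is malformed (e.g., a cyclic parent chain)."""


class ConfigurationError(ValueError):
    """Bad reference-set configuration."""


@dataclass
class TaxonNode:
    """One accepted entry of a taxonomic reference.

    ``lineage`` lists ancestor ids root→parent; ``lineage_ranks`` is aligned
    with it. ``status`` is ``accepted`` or ``doubtful`` (doubtful rows are
    retained but flagged).
    """

    taxon_id: str
    canonical_name: str
    rank: str
    parent_id: str = ""
    lineage: list[str] = field(default_factory=list)
    lineage_ranks: list[str] = field(default_factory=list)
    synonyms: list[str] = field(default_factory=list)
    status: str = "accepted"

    @property
    def first_block(self) -> str:
        return self.canonical_name.split()[0] if self.canonical_name else ""


class ParseResult(Mapping):
    """Accepted nodes by id, plus the count of dropped records.

    Behaves as a read-only mapping ``taxon_id -> TaxonNode``; records whose
    accepted target (or canonical name) was missing are not present and are
    tallied in :attr:`dropped`.
    """

    def __init__(self, nodes: dict[str, TaxonNode], dropped: int = 0):
        self.nodes = nodes
        self.dropped = dropped

    def __getitem__(self, key: str) -> TaxonNode:
        return self.nodes[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)


def _clean_name(name: str, config: MapperConfig) -> str:
    """Strip authority/parentheticals from a reference name; keep original
    on content-free results (never discard a name at parse time)."""
    try:
        return simple_correct(name, config)
    except ContentFreeInputError:
        return name.strip()


def _as_text(stream) -> io.TextIOBase:
    """Accept a path (plain or .gz), bytes, or a binary/text stream."""
    if isinstance(stream, (str, Path)):
        p = Path(stream)
        if p.suffix == ".gz":
            return io.TextIOWrapper(gzip.open(p, "rb"), encoding="utf-8")
        return open(p, "r", encoding="utf-8")
    if isinstance(stream, bytes):
        return io.StringIO(stream.decode("utf-8"))
    if isinstance(stream, io.TextIOBase):
        return stream
    return io.TextIOWrapper(stream, encoding="utf-8")


# ---------------------------------------------------------------------------
# NCBI taxdump
# ---------------------------------------------------------------------------

#: names.dmp name classes treated as synonyms of the accepted entry.
_NCBI_SYNONYM_CLASSES = {
    "synonym",
    "equivalent name",
    "includes",
    "genbank synonym",
}


def _split_dmp(line: str) -> list[str]:
    return line.rstrip("\n").rstrip("\t|").split("\t|\t")


def _parse_ncbi(files: Mapping, config: MapperConfig) -> ParseResult:
    if "names" not in files or "nodes" not in files:
        raise DialectError("ncbi-taxdump requires both 'names' and 'nodes' streams")

    parents: dict[str, str] = {}
    ranks: dict[str, str] = {}
    with _as_text(files["nodes"]) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _split_dmp(line)
            if len(fields) < 3:
                raise DialectError(
                    "nodes.dmp record needs tax_id | parent | rank fields"
                )
            tid, parent, rank = fields[0].strip(), fields[1].strip(), fields[2].strip()
            parents[tid] = "" if parent == tid else parent
            ranks[tid] = rank

    canonical: dict[str, str] = {}
    synonyms: dict[str, list[str]] = {}
    with _as_text(files["names"]) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _split_dmp(line)
            if len(fields) < 4:
                raise DialectError(
                    "names.dmp record needs tax_id | name | unique name | class fields"
                )
            tid = fields[0].strip()
            name = _clean_name(fields[1], config)
            name_class = fields[3].strip().casefold()
            if name_class == "scientific name":
                canonical[tid] = name
            elif name_class in _NCBI_SYNONYM_CLASSES:
                synonyms.setdefault(tid, []).append(name)
            # common names / authority etc. are ignored

    nodes: dict[str, TaxonNode] = {}
    dropped = 0
    for tid in parents:
        name = canonical.get(tid)
        if not name:
            dropped += 1
            continue
        syns = []
        for s in synonyms.get(tid, []):
            if s != name and s not in syns:
                syns.append(s)
        nodes[tid] = TaxonNode(
            taxon_id=tid,
            canonical_name=name,
            rank=ranks.get(tid, "no rank"),
            parent_id=parents[tid],
            synonyms=syns,
        )
    dropped += sum(1 for tid in canonical if tid not in parents)
    _materialize_lineages(nodes)
    return ParseResult(nodes, dropped)


# ---------------------------------------------------------------------------
# Darwin-Core taxon tables
# ---------------------------------------------------------------------------

_DWC_REQUIRED = (
    "taxonID",
    "scientificName",
    "taxonRank",
    "parentNameUsageID",
    "acceptedNameUsageID",
    "taxonomicStatus",
)

_DWC_SYNONYM_STATUSES = {"synonym", "misapplied"}


def _parse_dwc(files, config: MapperConfig) -> ParseResult:
    if isinstance(files, Mapping):
        stream = files.get("taxon")
        if stream is None:
            raise DialectError("dwc-taxon requires a 'taxon' stream")
    else:
        stream = files

    with _as_text(stream) as fh:
        reader = csv.DictReader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        header = reader.fieldnames or []
        for col in _DWC_REQUIRED:
            if col not in header:
                raise DialectError(f"dwc-taxon table is missing column {col!r}")
        rows = [row for row in reader if any((v or "").strip() for v in row.values())]

    nodes: dict[str, TaxonNode] = {}
    synonym_rows: list[dict] = []
    dropped = 0
    for row in rows:
        tid = (row["taxonID"] or "").strip()
        name = _clean_name(row["scientificName"] or "", config)
        status = (row["taxonomicStatus"] or "").strip().casefold()
        accepted_id = (row["acceptedNameUsageID"] or "").strip()
        if not tid or not name:
            dropped += 1
            continue
        is_synonym = (
            status in _DWC_SYNONYM_STATUSES
            or ("synonym" in status)
            or (accepted_id and accepted_id != tid and status not in ("accepted", "valid", "doubtful"))
        )
        if is_synonym:
            synonym_rows.append(row)
        else:
            nodes[tid] = TaxonNode(
                taxon_id=tid,
                canonical_name=name,
                rank=(row["taxonRank"] or "no rank").strip() or "no rank",
                parent_id=(row["parentNameUsageID"] or "").strip(),
                status="doubtful" if status == "doubtful" else "accepted",
            )

    for row in synonym_rows:
        accepted_id = (row["acceptedNameUsageID"] or "").strip()
        target = nodes.get(accepted_id)
        if target is None:
            dropped += 1
            continue
        name = _clean_name(row["scientificName"] or "", config)
        if name and name != target.canonical_name and name not in target.synonyms:
            target.synonyms.append(name)

    # parent pointers may reference synonym rows in sloppy exports; remap
    # them through the accepted target where possible, else cut the chain.
    for node in nodes.values():
        if node.parent_id and node.parent_id not in nodes:
            node.parent_id = ""
    _materialize_lineages(nodes)
    return ParseResult(nodes, dropped)


def _materialize_lineages(nodes: dict[str, TaxonNode]) -> None:
    """Fill lineage/lineage_ranks by walking parent links (cycle-checked)."""
    cache: dict[str, list[str]] = {}

    def chain(tid: str) -> list[str]:
        if tid in cache:
            return cache[tid]
        path: list[str] = []
        seen: set[str] = set()
        cur = nodes[tid].parent_id
        while cur:
            if cur in seen:
                raise StructuralError(f"cyclic parent chain involving taxon {cur!r}")
            if cur not in nodes:
                break
            seen.add(cur)
            path.append(cur)
            hit = cache.get(cur)
            if hit is not None:
                path.extend(hit)
                break
            cur = nodes[cur].parent_id
        cache[tid] = path
        return path

    for tid, node in nodes.items():
        # chain() returns parent→root; lineage is stored root→parent
        up = chain(tid)
        node.lineage = list(reversed(up))
        node.lineage_ranks = [nodes[a].rank for a in node.lineage]


def parse_reference(
    dialect: str, files, config: MapperConfig = DEFAULT_CONFIG
) -> ParseResult:
    """Parse a reference dump in the given dialect into accepted nodes.

    ``files`` is a mapping of role → path/stream (``names``/``nodes`` for
    ``ncbi-taxdump``; ``taxon`` for ``dwc-taxon``, where a bare path is also
    accepted).
    """
    if dialect == "ncbi-taxdump":
        if not isinstance(files, Mapping):
            raise DialectError("ncbi-taxdump requires a mapping of names/nodes streams")
        return _parse_ncbi(files, config)
    if dialect == "dwc-taxon":
        return _parse_dwc(files, config)
    raise DialectError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Indexing
# ---------------------------------------------------------------------------

def build_indexes(
    nodes: Mapping[str, TaxonNode],
) -> tuple[dict[str, list[tuple[str, bool]]], dict[str, list[str]]]:
    """Build the case-folded full-name and first-word-block indexes.

    ``name_index`` maps a case-folded name to ``[(taxon_id, is_synonym)]``;
    ``genus_index`` maps the case-folded first word-block of every canonical
    name and synonym to the taxon ids bearing it. Values are sorted by
    taxon id for determinism.
    """
    name_index: dict[str, list[tuple[str, bool]]] = {}
    genus_index: dict[str, set[str]] = {}
    for tid, node in nodes.items():
        for name, is_syn in [(node.canonical_name, False)] + [
            (s, True) for s in node.synonyms
        ]:
            key = name.casefold()
            entry = (tid, is_syn)
            bucket = name_index.setdefault(key, [])
            if entry not in bucket:
                bucket.append(entry)
            first = name.split()[0].casefold() if name.split() else ""
            if first:
                genus_index.setdefault(first, set()).add(tid)
    for bucket in name_index.values():
        bucket.sort()
    return name_index, {k: sorted(v) for k, v in genus_index.items()}


@dataclass
class Reference:
    """A parsed reference with its indexes."""

    name: str
    nodes: dict[str, TaxonNode]
    name_index: dict[str, list[tuple[str, bool]]] = field(default_factory=dict)
    genus_index: dict[str, list[str]] = field(default_factory=dict)
    dropped: int = 0

    @classmethod
    def from_nodes(cls, name: str, nodes: Mapping[str, TaxonNode], dropped: int = 0):
        name_index, genus_index = build_indexes(nodes)
        return cls(name=name, nodes=dict(nodes), name_index=name_index,
                   genus_index=genus_index, dropped=dropped)

    def lookup(self, name: str) -> list[tuple[str, bool]]:
        """Case-insensitive name lookup → [(taxon_id, is_synonym)]."""
        return self.name_index.get(name.casefold(), [])

    def node(self, taxon_id: str) -> TaxonNode:
        return self.nodes[taxon_id]


@dataclass
class ReferenceSet:
    """Several named references plus the pooled valid-name list."""

    references: dict[str, Reference] = field(default_factory=dict)

    @property
    def valid_names(self) -> set[str]:
        """Case-folded union of canonical names and synonyms across all
        references — any name recognized as valid somewhere."""
        pooled: set[str] = set()
        for ref in self.references.values():
            pooled.update(ref.name_index)
        return pooled

    def __getitem__(self, name: str) -> Reference:
        return self.references[name]

    def __iter__(self) -> Iterator[Reference]:
        return iter(self.references.values())

    def __len__(self) -> int:
        return len(self.references)

    def others(self, target: str) -> list[Reference]:
        return [r for n, r in self.references.items() if n != target]

    def add(self, ref: Reference) -> None:
        if ref.name in self.references:
            raise ConfigurationError(f"duplicate reference name {ref.name!r}")
        self.references[ref.name] = ref


def load_reference_set(
    config: Sequence[tuple[str, str, object]],
    mapper_config: MapperConfig = DEFAULT_CONFIG,
) -> ReferenceSet:
    """Load several references from ``(name, dialect, files)`` entries."""
    if not config:
        raise ConfigurationError("at least one reference must be configured")
    refset = ReferenceSet()
    for name, dialect, files in config:
        if name in refset.references:
            raise ConfigurationError(f"duplicate reference name {name!r}")
        for p in _iter_paths(files):
            if not Path(p).exists():
                raise ConfigurationError(f"reference {name!r}: missing file {p}")
        result = parse_reference(dialect, files, mapper_config)
        refset.add(Reference.from_nodes(name, result.nodes, result.dropped))
    return refset


def _iter_paths(files) -> Iterator[str | Path]:
    if isinstance(files, (str, Path)):
        yield files
    elif isinstance(files, Mapping):
        for v in files.values():
            if isinstance(v, (str, Path)):
                yield v
    elif isinstance(files, (list, tuple)):
        for v in files:
            if isinstance(v, (str, Path)):
                yield v


# ---------------------------------------------------------------------------
# Preprocessed reference caches
# ---------------------------------------------------------------------------

_LIST_SEP = "|"


def write_cache(ref: Reference, directory: str | Path) -> tuple[Path, Path]:
    """Write ``<name>_node_dict.txt`` / ``<name>_genus_dict.txt`` caches.

    Tab-separated, one node per row; round-trips exactly through
    :func:`read_cache`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    node_path = directory / f"{ref.name}_node_dict.txt"
    genus_path = directory / f"{ref.name}_genus_dict.txt"
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("taxon_id\tcanonical_name\trank\tparent_id\t"
                 "lineage\tlineage_ranks\tsynonyms\tstatus\n")
        for tid in sorted(ref.nodes):
            n = ref.nodes[tid]
            fh.write("\t".join([
                n.taxon_id,
                n.canonical_name,
                n.rank,
                n.parent_id,
                _LIST_SEP.join(n.lineage),
                _LIST_SEP.join(n.lineage_ranks),
                _LIST_SEP.join(n.synonyms),
                n.status,
            ]) + "\n")
    with open(genus_path, "w", encoding="utf-8") as fh:
        for block in sorted(ref.genus_index):
            fh.write(f"{block}\t{_LIST_SEP.join(ref.genus_index[block])}\n")
    return node_path, genus_path


def read_cache(name: str, directory: str | Path) -> Reference:
    """Reload a reference from its cache files (indexes are rebuilt)."""
    node_path = Path(directory) / f"{name}_node_dict.txt"
    nodes: dict[str, TaxonNode] = {}
    with open(node_path, encoding="utf-8") as fh:
        next(fh)  # header
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            (tid, cname, rank, parent, lineage, lineage_ranks,
             synonyms, status) = line.split("\t")
            nodes[tid] = TaxonNode(
                taxon_id=tid,
                canonical_name=cname,
                rank=rank,
                parent_id=parent,
                lineage=lineage.split(_LIST_SEP) if lineage else [],
                lineage_ranks=lineage_ranks.split(_LIST_SEP) if lineage_ranks else [],
                synonyms=synonyms.split(_LIST_SEP) if synonyms else [],
                status=status,
            )
    return Reference.from_nodes(name, nodes)


# ---------------------------------------------------------------------------
# Download helpers (convenience only; never exercised by the test suite)
# ---------------------------------------------------------------------------

REFERENCE_URLS = {
    "col": "https://download.checklistbank.org/col/",
    "eol": "https://opendata.eol.org/dataset/tram-807-808-809-810-dh-v1-1/",
    "gbif": "https://hosted-datasets.gbif.org/datasets/backbone/current/",
    "ncbi": "https://ftp.ncbi.nih.gov/pub/taxonomy/",
}


def download_reference(url: str, dest: str | Path, timeout: float = 60.0) -> Path:
    """Fetch a reference archive to ``dest`` (requires network access)."""
    dest = Path(dest)
    dest.parent.mkdir(parents=True, exist_ok=True)
    with urllib.request.urlopen(url, timeout=timeout) as resp, open(dest, "wb") as out:
        while chunk := resp.read(1 << 20):
            out.write(chunk)
    return dest
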