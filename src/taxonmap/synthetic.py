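"""Synthetic reference and query generators.

Miniature taxonomies (writable in every supported dialect), typo
injection, and natural-product pair tables with a planned support
histogram — so every downstream accuracy measurement has an exact expected
value by construction, with no external downloads.

Generated species names are pronounceable Latin-like binomials kept at a
pairwise edit distance of at least ``2·max_d + 1`` (7 with the default
threshold), which makes recovery from up to ``max_d`` injected typos
unambiguous. A configurable near-duplicate rate deliberately breaks that
guarantee to exercise multi-match behaviour.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .engine import damerau_levenshtein
from .reference_io import TaxonNode, _materialize_lineages

__all__ = [
    "FixtureSpecError",
    "FixtureSpec",
    "GeneratedReference",
    "build_taxonomy",
    "write_reference",
    "generate_reference_fixture",
    "generate_reference_set",
    "inject_typos",
    "make_typo_testset",
    "NPPairPlan",
    "NPPairResult",
    "generate_np_pairs",
]


class FixtureSpecError(ValueError):
    """The requested fixture is internally impossible."""


_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"

#: Minimum pairwise edit distance between distinct species-level names.
MIN_NAME_SEPARATION = 7
_GENUS_SEPARATION = 3


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic reference.

    Defaults give a mid-sized desk fixture: 600 species in 120 genera over
    three domains of life, with a 30% synonym rate (roughly the synonym
    richness of real checklists) and no planted ambiguities.
    """

    n_species: int = 600
    n_genera: int = 120
    domains: tuple[tuple[str, float], ...] = (
        ("Plantae", 0.5),
        ("Animalia", 0.3),
        ("Bacteria", 0.2),
    )
    synonym_rate: float = 0.3
    hemihomonym_pairs: int = 0
    shared_fraction: float = 0.5
    near_duplicate_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_species <= 0 or self.n_genera <= 0:
            raise FixtureSpecError("counts must be positive")
        for _, p in self.domains:
            if not 0.0 <= p <= 1.0:
                raise FixtureSpecError("domain proportions must be in [0, 1]")
        for rate in (self.synonym_rate, self.shared_fraction,
                     self.near_duplicate_rate):
            if not 0.0 <= rate <= 1.0:
                raise FixtureSpecError("rates must be in [0, 1]")
        if self.hemihomonym_pairs * 2 > self.n_genera:
            raise FixtureSpecError(
                "more hemihomonym pairs than genus slots can carry"
            )
        if self.hemihomonym_pairs > 0 and len(self.domains) < 2:
            raise FixtureSpecError("hemihomonyms need at least two domains")
        if self.n_species < self.n_genera:
            raise FixtureSpecError("need at least one species per genus")


def _syllable(rng: random.Random) -> str:
    return rng.choice(_CONSONANTS) + rng.choice(_VOWELS)


def _word(rng: random.Random, n_syllables: int) -> str:
    return "".join(_syllable(rng) for _ in range(n_syllables))


def _min_distance(name: str, pool: Sequence[str], cap: int) -> int:
    best = cap + 1
    for other in pool:
        if abs(len(other) - len(name)) > cap:
            continue
        d = damerau_levenshtein(name, other, cap)
        if d < best:
            best = d
            if best == 0:
                break
    return best


def _fresh_name(
    rng: random.Random,
    make: callable,
    pool: Sequence[str],
    separation: int,
    attempts: int = 400,
) -> str:
    for _ in range(attempts):
        cand = make(rng)
        if _min_distance(cand, pool, separation - 1) >= separation:
            return cand
    raise FixtureSpecError(
        "could not generate a sufficiently separated name; "
        "the requested fixture is too dense"
    )


@dataclass
class GeneratedReference:
    """Ground truth for one generated reference."""

    nodes: dict[str, TaxonNode]
    species_ids: list[str]
    hemihomonym_names: list[str]
    near_duplicate_ids: list[str]
    paths: dict[str, Path] = field(default_factory=dict)

    def species_names(self) -> list[str]:
        return [self.nodes[t].canonical_name for t in self.species_ids]


def build_taxonomy(spec: FixtureSpec) -> GeneratedReference:
    """Construct the ground-truth node set for a spec (no files written).

    Hierarchy: root → kingdom → family → genus → species; every identifier
    and name is drawn deterministically from ``spec.seed``.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    next_id = [1]

    def new_id() -> str:
        tid = str(next_id[0])
        next_id[0] += 1
        return tid

    nodes: dict[str, TaxonNode] = {}
    root_id = new_id()
    nodes[root_id] = TaxonNode(root_id, "root", "no rank", "")

    kingdom_ids: dict[str, str] = {}
    for label, _ in spec.domains:
        kid = new_id()
        nodes[kid] = TaxonNode(kid, label, "kingdom", root_id)
        kingdom_ids[label] = kid

    # genus -> kingdom assignment by the requested proportions
    labels = [label for label, _ in spec.domains]
    weights = [p for _, p in spec.domains]
    genus_domains = rng.choices(labels, weights=weights, k=spec.n_genera)
    # hemihomonym twins must straddle two distinct domains
    for i in range(spec.hemihomonym_pairs):
        genus_domains[2 * i] = labels[0]
        genus_domains[2 * i + 1] = labels[1]

    all_names: list[str] = []  # species-level names, separation-enforced
    short_names: list[str] = []  # genus/family names, uniqueness-enforced

    # one family per ~4 genera, per kingdom
    family_of_kingdom: dict[str, list[str]] = {}
    n_families = max(1, spec.n_genera // 4)
    family_names = []
    for _ in range(n_families):
        fname = _fresh_name(
            rng, lambda r: _word(r, 3).capitalize() + "idae",
            family_names + all_names, _GENUS_SEPARATION,
        )
        family_names.append(fname)
    for i, fname in enumerate(family_names):
        label = labels[i % len(labels)]
        fid = new_id()
        nodes[fid] = TaxonNode(fid, fname, "family", kingdom_ids[label])
        family_of_kingdom.setdefault(label, []).append(fid)
    for label in labels:  # every kingdom needs at least one family
        if label not in family_of_kingdom:
            fname = _fresh_name(
                rng, lambda r: _word(r, 3).capitalize() + "idae",
                family_names, _GENUS_SEPARATION,
            )
            family_names.append(fname)
            fid = new_id()
            nodes[fid] = TaxonNode(fid, fname, "family", kingdom_ids[label])
            family_of_kingdom[label] = [fid]
    short_names.extend(family_names)

    genus_ids: list[str] = []
    genus_names: list[str] = []
    hemihomonym_names: list[str] = []
    for i in range(spec.n_genera):
        if spec.hemihomonym_pairs and i < 2 * spec.hemihomonym_pairs and i % 2 == 1:
            gname = genus_names[i - 1]  # twin genus: same name, other domain
            if gname not in hemihomonym_names:
                hemihomonym_names.append(gname)
        else:
            gname = _fresh_name(
                rng, lambda r: _word(r, 3).capitalize(),
                genus_names + short_names, _GENUS_SEPARATION,
            )
        genus_names.append(gname)
        label = genus_domains[i]
        gid = new_id()
        fam = rng.choice(family_of_kingdom[label])
        nodes[gid] = TaxonNode(gid, gname, "genus", fam)
        genus_ids.append(gid)
    short_names.extend(genus_names)

    # distribute species: one per genus first, the rest at random
    assignment = list(range(spec.n_genera))
    assignment += rng.choices(range(spec.n_genera),
                              k=spec.n_species - spec.n_genera)

    species_ids: list[str] = []
    near_duplicate_ids: list[str] = []
    for gi in assignment:
        genus = nodes[genus_ids[gi]]
        make = lambda r, g=genus.canonical_name: f"{g} {_word(r, rng.randint(4, 6))}"
        name = _fresh_name(rng, make, all_names, MIN_NAME_SEPARATION)
        all_names.append(name)
        sid = new_id()
        nodes[sid] = TaxonNode(sid, name, "species", genus.taxon_id)
        species_ids.append(sid)
        if rng.random() < spec.synonym_rate:
            syn = _fresh_name(rng, make, all_names, MIN_NAME_SEPARATION)
            all_names.append(syn)
            nodes[sid].synonyms.append(syn)
        if rng.random() < spec.near_duplicate_rate:
            # sibling species within typo range of this one
            base = name.split(" ", 1)[1]
            sibling = None
            for _ in range(50):
                cand_ep = inject_typos(base, rng.randint(1, 2), rng=rng)
                cand = f"{genus.canonical_name} {cand_ep}"
                if cand not in all_names and cand != name:
                    sibling = cand
                    break
            if sibling is not None:
                all_names.append(sibling)
                did = new_id()
                nodes[did] = TaxonNode(did, sibling, "species", genus.taxon_id)
                species_ids.append(did)
                near_duplicate_ids.extend([sid, did])

    _materialize_lineages(nodes)
    return GeneratedReference(
        nodes=nodes,
        species_ids=species_ids,
        hemihomonym_names=hemihomonym_names,
        near_duplicate_ids=sorted(set(near_duplicate_ids)),
    )


# ---------------------------------------------------------------------------
# Dialect writers
# ---------------------------------------------------------------------------

def _write_ncbi(nodes: Mapping[str, TaxonNode], outdir: Path) -> dict[str, Path]:
    names_path = outdir / "names.dmp"
    nodes_path = outdir / "nodes.dmp"
    order = sorted(nodes, key=lambda t: int(t) if t.isdigit() else t)
    with open(nodes_path, "w", encoding="utf-8") as fh:
        for tid in order:
            n = nodes[tid]
            parent = n.parent_id or tid  # NCBI roots point at themselves
            fh.write(f"{tid}\t|\t{parent}\t|\t{n.rank}\t|\n")
    with open(names_path, "w", encoding="utf-8") as fh:
        for tid in order:
            n = nodes[tid]
            fh.write(f"{tid}\t|\t{n.canonical_name}\t|\t\t|\tscientific name\t|\n")
            for syn in n.synonyms:
                fh.write(f"{tid}\t|\t{syn}\t|\t\t|\tsynonym\t|\n")
    return {"names": names_path, "nodes": nodes_path}


def _write_dwc(nodes: Mapping[str, TaxonNode], outdir: Path) -> dict[str, Path]:
    path = outdir / "Taxon.tsv"
    order = sorted(nodes, key=lambda t: int(t) if t.isdigit() else t)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("taxonID\tscientificName\ttaxonRank\tparentNameUsageID\t"
                 "acceptedNameUsageID\ttaxonomicStatus\n")
        syn_counter = 1
        for tid in order:
            n = nodes[tid]
            fh.write(f"{tid}\t{n.canonical_name}\t{n.rank}\t{n.parent_id}\t"
                     f"\t{n.status}\n")
            for syn in n.synonyms:
                fh.write(f"SYN{syn_counter}\t{syn}\tspecies\t\t{tid}\tsynonym\n")
                syn_counter += 1
    return {"taxon": path}


_WRITERS = {"ncbi-taxdump": _write_ncbi, "dwc-taxon": _write_dwc}


def write_reference(
    nodes: Mapping[str, TaxonNode], dialect: str, outdir: str | Path
) -> dict[str, Path]:
    """Emit a node set in a dialect ``reference_io.parse_reference`` reads."""
    if dialect not in _WRITERS:
        raise FixtureSpecError(f"unknown dialect {dialect!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return _WRITERS[dialect](nodes, outdir)


def generate_reference_fixture(
    spec: FixtureSpec, dialect: str, outdir: str | Path
) -> GeneratedReference:
    """Generate a taxonomy and write it to disk in the requested dialect.

    Identical spec + seed produce byte-identical files.
    """
    truth = build_taxonomy(spec)
    truth.paths = write_reference(truth.nodes, dialect, outdir)
    return truth


def generate_reference_set(
    spec: FixtureSpec,
    dialects: Mapping[str, str],
    outdir: str | Path,
) -> tuple[dict[str, GeneratedReference], GeneratedReference]:
    """Write several references drawn from one master taxonomy.

    A ``shared_fraction`` core of the species is present in every reference;
    the remaining species are partitioned round-robin so each reference also
    holds names unique to it. Returns (per-reference truths, master truth).
    """
    master = build_taxonomy(spec)
    ref_names = list(dialects)
    n_shared = round(spec.shared_fraction * len(master.species_ids))
    shared = set(master.species_ids[:n_shared])
    rest = master.species_ids[n_shared:]
    exclusive: dict[str, set[str]] = {rn: set() for rn in ref_names}
    for i, sid in enumerate(rest):
        exclusive[ref_names[i % len(ref_names)]].add(sid)

    out: dict[str, GeneratedReference] = {}
    for rn in ref_names:
        keep = shared | exclusive[rn]
        nodes = {
            tid: replace_node(node)
            for tid, node in master.nodes.items()
            if node.rank != "species" or tid in keep
        }
        _materialize_lineages(nodes)
        truth = GeneratedReference(
            nodes=nodes,
            species_ids=[s for s in master.species_ids if s in keep],
            hemihomonym_names=list(master.hemihomonym_names),
            near_duplicate_ids=[
                s for s in master.near_duplicate_ids if s in keep
            ],
        )
        truth.paths = write_reference(nodes, dialects[rn], Path(outdir) / rn)
        out[rn] = truth
    return out, master


def replace_node(node: TaxonNode) -> TaxonNode:
    """Deep-ish copy of a node (lists copied, strings shared)."""
    return TaxonNode(
        taxon_id=node.taxon_id,
        canonical_name=node.canonical_name,
        rank=node.rank,
        parent_id=node.parent_id,
        lineage=list(node.lineage),
        lineage_ranks=list(node.lineage_ranks),
        synonyms=list(node.synonyms),
        status=node.status,
    )


# ---------------------------------------------------------------------------
# Typo injection
# ---------------------------------------------------------------------------

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def inject_typos(
    name: str,
    k: int,
    seed: int | None = None,
    rng: random.Random | None = None,
    preserve_first: bool = True,
) -> str:
    """Apply ``k`` random edit operations (substitution, insertion,
    deletion, adjacent transposition) to a name.

    The first character is preserved by default so that first-word-block
    candidate pruning stays exercised rather than trivially bypassed. The
    result is guaranteed to satisfy ``damerau_levenshtein(name, out) <= k``
    (operations are re-drawn in the rare case edits interact to exceed it).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if len(name) <= k:
        raise ValueError("name must be longer than k")
    if k == 0:
        return name
    if rng is None:
        rng = random.Random(seed)
    lo = 1 if preserve_first else 0

    for _ in range(100):
        chars = list(name)
        for _ in range(k):
            op = rng.choice(("substitute", "insert", "delete", "transpose"))
            if op == "substitute":
                pos = rng.randrange(lo, len(chars))
                old = chars[pos]
                choices = [c for c in _ALPHABET if c != old.lower()]
                new = rng.choice(choices)
                chars[pos] = new.upper() if old.isupper() else new
            elif op == "insert":
                pos = rng.randrange(lo, len(chars) + 1)
                chars.insert(pos, rng.choice(_ALPHABET))
            elif op == "delete" and len(chars) > lo + 1:
                pos = rng.randrange(lo, len(chars))
                chars.pop(pos)
            elif op == "transpose":
                positions = [
                    i for i in range(lo, len(chars) - 1)
                    if chars[i] != chars[i + 1]
                ]
                if positions:
                    i = rng.choice(positions)
                    chars[i], chars[i + 1] = chars[i + 1], chars[i]
        out = "".join(chars)
        if damerau_levenshtein(name, out) <= k:
            return out
    raise RuntimeError("typo injection failed to stay within the edit budget")


def make_typo_testset(
    truth: GeneratedReference,
    k: int,
    seed: int,
    n: int | None = None,
    outpath: str | Path | None = None,
) -> list[tuple[str, str, str, int]]:
    """Corrupt species names with ``k`` typos each.

    Returns ``(corrupted, original_name, taxon_id, k)`` rows; optionally
    writes them as the ground-truth TSV.
    """
    rng = random.Random(seed)
    ids = truth.species_ids if n is None else rng.sample(
        truth.species_ids, min(n, len(truth.species_ids))
    )
    rows = []
    for tid in ids:
        name = truth.nodes[tid].canonical_name
        rows.append((inject_typos(name, k, rng=rng), name, tid, k))
    if outpath is not None:
        with open(outpath, "w", encoding="utf-8") as fh:
            fh.write("corrupted\toriginal\ttaxon_id\tk\n")
            for row in rows:
                fh.write("\t".join(map(str, row)) + "\n")
    return rows


# ---------------------------------------------------------------------------
# NP occurrence pair tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NPPairPlan:
    """Planned composition of synthetic species–compound pair tables.

    ``support_plan`` maps a degree of support (number of source databases
    reporting a pair) to the number of pairs planned at that support.
    Perturbation rates control how often a source spells the species name
    as a typo'd, Latin-inflected, strain-suffixed or vernacular variant.
    """

    support_plan: Mapping[int, int] = field(
        default_factory=lambda: {1: 12, 2: 6, 3: 3, 4: 2}
    )
    sources: tuple[str, ...] = ("npdb_a", "npdb_b", "npdb_c", "npdb_d")
    typo_rate: float = 0.0
    declension_rate: float = 0.0
    strain_rate: float = 0.0
    vernacular_rate: float = 0.0
    n_unmappable: int = 0
    seed: int = 0


@dataclass
class NPPairResult:
    """Generated tables plus the ground truth they were built from."""

    tables: dict[str, list[tuple[str, str]]]
    expected: dict[tuple[str, str], int]  # (taxon_id, structure) -> support
    vernacular_map: dict[str, str]
    n_unmappable: int
    paths: dict[str, Path] = field(default_factory=dict)


def _inflect(name: str) -> str:
    """Latin-genitive / materia-medica style variant of a binomial.

    Inflections are chosen so the declension table can reconstruct the
    nominative: final '-a' → '-ae', final '-e' → '-is'; a part term is
    always appended.
    """
    blocks = []
    for b in name.split():
        if b.endswith("a"):
            blocks.append(b + "e")  # -a -> -ae
        elif b.endswith("e"):
            blocks.append(b[:-1] + "is")
        else:
            blocks.append(b)
    return " ".join(blocks) + " radix"


def generate_np_pairs(
    truth: GeneratedReference,
    plan: NPPairPlan,
    outdir: str | Path | None = None,
) -> NPPairResult:
    """Emit 2–4 source tables of (name, structure) with known ground truth.

    Cross-source overlap follows ``plan.support_plan`` exactly, so the
    integrated support histogram has an exact expected value. Unmappable
    extras are '<Genus> sp.' entries that cannot reach species level.
    """
    rng = random.Random(plan.seed)
    if max(plan.support_plan, default=1) > len(plan.sources):
        raise FixtureSpecError("support exceeds the number of sources")
    n_pairs = sum(plan.support_plan.values())
    if not truth.species_ids:
        raise FixtureSpecError("truth carries no species")

    structures: set[str] = set()

    def new_structure() -> str:
        while True:
            s = "".join(rng.choice("CNO") for _ in range(rng.randint(4, 10)))
            if s not in structures:
                structures.add(s)
                return s

    tables: dict[str, list[tuple[str, str]]] = {s: [] for s in plan.sources}
    expected: dict[tuple[str, str], int] = {}
    vmap: dict[str, str] = {}
    vern_counter = [0]

    def spell(name: str) -> str:
        r = rng.random()
        if r < plan.typo_rate:
            return inject_typos(name, 1, rng=rng)
        r -= plan.typo_rate
        if r < plan.declension_rate:
            return _inflect(name)
        r -= plan.declension_rate
        if r < plan.strain_rate:
            code = "".join(rng.choice("BCDKST") for _ in range(3))
            return f"{name} {code}-{rng.randint(10, 999)}"
        r -= plan.strain_rate
        if r < plan.vernacular_rate:
            vern_counter[0] += 1
            v = f"herbname{vern_counter[0]}"
            vmap[v.casefold()] = name
            return v
        return name

    species_cycle = list(truth.species_ids)
    pair_no = 0
    for support, count in sorted(plan.support_plan.items()):
        for _ in range(count):
            sid = species_cycle[pair_no % len(species_cycle)]
            pair_no += 1
            name = truth.nodes[sid].canonical_name
            structure = new_structure()
            expected[(sid, structure)] = support
            chosen = rng.sample(plan.sources, support)
            for src in chosen:
                tables[src].append((spell(name), structure))

    genus_ids = sorted(
        {truth.nodes[s].parent_id for s in truth.species_ids}
    )
    for i in range(plan.n_unmappable):
        gname = truth.nodes[genus_ids[i % len(genus_ids)]].canonical_name
        tables[plan.sources[i % len(plan.sources)]].append(
            (f"{gname} sp.", new_structure())
        )

    result = NPPairResult(
        tables=tables,
        expected=expected,
        vernacular_map=vmap,
        n_unmappable=plan.n_unmappable,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for src, rows in tables.items():
            p = outdir / f"{src}.tsv"
            with open(p, "w", encoding="utf-8") as fh:
                fh.write("name\tstructure\n")
                for name, structure in rows:
                    fh.write(f"{name}\t{structure}\n")
            result.paths[src] = p
    return result
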