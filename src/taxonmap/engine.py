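"""The scientific-name mapping cascade.

Every query is resolved against a chosen target reference through an
ordered sequence of stages:

1. exact matching in the target (raw, simple-corrected, case-insensitive);
2. recursive synonym matching — names exactly matched in *other* references
   contribute their canonical names and synonyms as probes into the target;
3. nearest-taxon mapping — the matched entity's phylogenetic lineage is
   walked tip→root and the lowest-rank ancestor resolvable in the target is
   returned, with hemihomonymous genera disambiguated by agreement of the
   top-rank (domain/kingdom) lineage label;
4. rule-based dropout (virus/phytoplasma/… and hybrid queries carry no
   taxonomic signal of their own) and flagged-name nearest mapping for
   strain-coded, cf. and aff. inputs, which bypass edit-distance correction;
5. Damerau-Levenshtein correction of the specific epithet within the genus
   bucket, then of the whole input (including Latin declension expansion);
6. partial mapping on word-block prefixes.

A name that is valid in at least one reference is never subjected to
edit-distance correction — stages 2–3 fire first.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import codes
from .codes import (
    dropout_code,
    nearest_code,
    rank_tier,
)
from .config import DEFAULT_CONFIG, MapperConfig
from .preprocess import NameQuery, latin_candidates, make_query
from .reference_io import Reference, ReferenceSet, TaxonNode

__all__ = [
    "damerau_levenshtein",
    "MappingRecord",
    "Outcome",
    "exact_match",
    "recursive_match",
    "nearest_taxon",
    "candidate_pool",
    "correct_epithet",
    "correct_whole",
    "strain_nearest",
    "partial_map",
    "map_name",
    "map_names",
]


# ---------------------------------------------------------------------------
# Distance primitive
# ---------------------------------------------------------------------------

def damerau_levenshtein(a: str, b: str, max_d: int | None = None) -> int:
    """Edit distance counting insertions, deletions, substitutions and
    adjacent transpositions (restricted / optimal-string-alignment form).

    With ``max_d`` set, returns ``max_d + 1`` as soon as the distance is
    known to exceed the cap (band shortcut for candidate pruning).
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if max_d is not None and abs(la - lb) > max_d:
        return max_d + 1
    if la == 0:
        return lb
    if lb == 0:
        return la

    prev2: list[int] | None = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ca = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ca == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and ca == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                d = min(d, prev2[j - 2] + 1)  # type: ignore[index]
            cur[j] = d
        if max_d is not None and min(cur) > max_d:
            return max_d + 1
        prev2, prev = prev, cur
    return prev[lb]


def _char_profile_diff(ca: Counter, cb: Counter) -> int:
    """Size of the symmetric multiset difference of two character profiles."""
    diff = 0
    for ch in ca.keys() | cb.keys():
        diff += abs(ca.get(ch, 0) - cb.get(ch, 0))
    return diff


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Outcome:
    """Per-reference result of the cascade."""

    status_code: int
    taxon_ids: tuple[str, ...]
    matched_name: str = ""
    matched_rank: str = ""
    distance: int = 0
    stage: str = ""


@dataclass(frozen=True)
class MappingRecord:
    """Full mapping result for one query against a target reference.

    ``others`` carries the best match found in every other loaded reference
    so a record shows whether an unmapped query is a valid name elsewhere.
    """

    query: NameQuery
    target: str
    status_code: int
    taxon_ids: tuple[str, ...]
    matched_name: str = ""
    matched_rank: str = ""
    distance: int = 0
    stage: str = ""
    others: Mapping[str, Outcome] = field(default_factory=dict)


def _resolve_entries(
    entries: Iterable[tuple[str, bool]]
) -> tuple[tuple[str, ...], bool]:
    """Collapse index entries to sorted unique taxon ids + synonym-ness.

    When a name is both canonical for one taxon and a synonym of another,
    canonical entries take precedence.
    """
    canon = sorted({tid for tid, is_syn in entries if not is_syn})
    if canon:
        return tuple(canon), False
    return tuple(sorted({tid for tid, _ in entries})), True


def _outcome_from_ids(
    ref: Reference,
    ids: Sequence[str],
    code: int,
    matched_name: str,
    distance: int,
    stage: str,
) -> Outcome:
    rank = ref.nodes[ids[0]].rank if ids else ""
    return Outcome(
        status_code=code,
        taxon_ids=tuple(ids),
        matched_name=matched_name,
        matched_rank=rank,
        distance=distance,
        stage=stage,
    )


# ---------------------------------------------------------------------------
# Stage 1: exact matching
# ---------------------------------------------------------------------------

def exact_match(query: NameQuery, ref: Reference) -> Outcome | None:
    """Exact match in one reference: raw form first, then the simple-corrected
    form, then case-insensitively. Returns ``None`` on no hit."""
    probes: list[tuple[str, bool, int, int]] = []
    raw = query.raw.strip()
    # (probe, case_sensitive, canonical_code, synonym_code)
    probes.append((raw, True, codes.EXACT_RAW_CANONICAL, codes.EXACT_RAW_SYNONYM))
    if query.normalized and query.normalized != raw:
        probes.append((query.normalized, True,
                       codes.EXACT_CORRECTED_CANONICAL, codes.EXACT_CORRECTED_SYNONYM))
    probes.append((raw, False,
                   codes.EXACT_CASEFOLD_CANONICAL, codes.EXACT_CASEFOLD_SYNONYM))
    if query.normalized and query.normalized != raw:
        probes.append((query.normalized, False,
                       codes.EXACT_CASEFOLD_CANONICAL, codes.EXACT_CASEFOLD_SYNONYM))

    for probe, case_sensitive, code_c, code_s in probes:
        if not probe:
            continue
        entries = ref.lookup(probe)
        if not entries:
            continue
        if case_sensitive:
            kept = []
            for tid, is_syn in entries:
                node = ref.nodes[tid]
                if not is_syn and node.canonical_name == probe:
                    kept.append((tid, is_syn))
                elif is_syn and probe in node.synonyms:
                    kept.append((tid, is_syn))
            if not kept:
                continue
            entries = kept
        ids, is_syn = _resolve_entries(entries)
        return _outcome_from_ids(
            ref, ids, code_s if is_syn else code_c, probe, 0, "exact"
        )
    return None


def _exact_sources(
    query: NameQuery, refset: ReferenceSet, target: str
) -> list[tuple[Reference, TaxonNode]]:
    """Accepted nodes exactly matching the query in references other than
    the target."""
    sources: list[tuple[Reference, TaxonNode]] = []
    for ref in refset.others(target):
        hit = exact_match(query, ref)
        if hit is not None:
            for tid in hit.taxon_ids:
                sources.append((ref, ref.nodes[tid]))
    return sources


# ---------------------------------------------------------------------------
# Stage 2: recursive synonym matching
# ---------------------------------------------------------------------------

def _names_of(node: TaxonNode) -> list[str]:
    return [node.canonical_name] + list(node.synonyms)


def recursive_match(
    sources: Sequence[tuple[Reference, TaxonNode]], target: Reference
) -> Outcome | None:
    """Probe the target with canonical names and synonyms of nodes matched
    in other references. Unique taxon → code 6, several distinct → 8."""
    hits: dict[str, str] = {}  # taxon_id -> probing name
    for _, node in sources:
        for name in _names_of(node):
            for tid, _ in target.lookup(name):
                hits.setdefault(tid, name)
    if not hits:
        return None
    ids = tuple(sorted(hits))
    code = codes.RECURSIVE_UNIQUE if len(ids) == 1 else codes.RECURSIVE_MULTIPLE
    return _outcome_from_ids(target, ids, code, hits[ids[0]], 0, "recursive")


# ---------------------------------------------------------------------------
# Stage 3: nearest-taxon mapping
# ---------------------------------------------------------------------------

def top_lineage_label(ref: Reference, node: TaxonNode) -> str:
    """Case-folded name of the highest-rank (domain/kingdom tier) lineage
    member, used to compare 'domains of life' across references."""
    for aid in node.lineage:
        anc = ref.nodes.get(aid)
        if anc is not None and rank_tier(anc.rank) in (6, 7):
            return anc.canonical_name.casefold()
    if rank_tier(node.rank) in (6, 7):
        return node.canonical_name.casefold()
    for aid in node.lineage[1:2]:  # first named child of the root
        anc = ref.nodes.get(aid)
        if anc is not None:
            return anc.canonical_name.casefold()
    return node.canonical_name.casefold()


def _pick_domain_consistent(
    candidate_ids: Sequence[str], target: Reference, source_label: str
) -> str:
    """Among homonymous target taxa, prefer the one sharing the source's
    top-rank lineage label; ties and misses fall back to the smallest id."""
    matching = [
        tid for tid in sorted(candidate_ids)
        if top_lineage_label(target, target.nodes[tid]) == source_label
    ]
    return matching[0] if matching else sorted(candidate_ids)[0]


def nearest_taxon(
    sources: Sequence[tuple[Reference, TaxonNode]], target: Reference
) -> Outcome | None:
    """Walk each matched node's lineage tip→root and return the lowest-rank
    ancestor resolvable in the target reference (codes 10–18)."""
    best: tuple[int, str, str] | None = None  # (tier, taxon_id, probe name)
    for src_ref, src_node in sources:
        src_label = top_lineage_label(src_ref, src_node)
        cur_tier = rank_tier(src_node.rank) or codes.SPECIES_TIER
        for ancestor_id in reversed(src_node.lineage):
            anc = src_ref.nodes.get(ancestor_id)
            if anc is None:
                continue
            tier = rank_tier(anc.rank)
            if tier is None:
                tier = cur_tier  # unranked: inherit nearest ranked descendant
            else:
                cur_tier = tier
            entries: list[tuple[str, bool]] = []
            for name in _names_of(anc):
                entries.extend(target.lookup(name))
            if not entries:
                continue
            ids, _ = _resolve_entries(entries)
            chosen = _pick_domain_consistent(ids, target, src_label)
            node_tier = rank_tier(target.nodes[chosen].rank)
            eff_tier = node_tier if node_tier is not None else tier
            key = (eff_tier, chosen, anc.canonical_name)
            if best is None or key < best:
                best = key
            break  # lowest-rank hit for this source found
    if best is None:
        return None
    tier, tid, probe = best
    return _outcome_from_ids(
        target, (tid,), nearest_code(tier), probe, 0, "nearest"
    )


# ---------------------------------------------------------------------------
# Stage 5a: epithet correction
# ---------------------------------------------------------------------------

def candidate_pool(
    name: str, ref: Reference, max_d: int = 3
) -> list[tuple[str, str, bool]]:
    """Candidate names sharing the query's first word-block, pre-filtered by
    length (≤ max_d) and character-profile difference (≤ 2·max_d).

    Returns ``(name, taxon_id, is_synonym)`` triples.
    """
    blocks = name.split()
    if not blocks:
        return []
    first = blocks[0].casefold()
    q = name.casefold()
    qc = Counter(q)
    out: list[tuple[str, str, bool]] = []
    for tid in ref.genus_index.get(first, []):
        node = ref.nodes[tid]
        for cand, is_syn in [(node.canonical_name, False)] + [
            (s, True) for s in node.synonyms
        ]:
            if not cand or cand.split()[0].casefold() != first:
                continue
            cl = cand.casefold()
            if abs(len(cl) - len(q)) > max_d:
                continue
            if _char_profile_diff(qc, Counter(cl)) > 2 * max_d:
                continue
            out.append((cand, tid, is_syn))
    return out


def _correction_code(kinds: set[bool], unique: bool, table: tuple[int, ...]) -> int:
    """Pick a code from (canon_unique, canon_multi, syn_unique, syn_multi,
    mixed_multi) based on hit kinds."""
    canon_u, canon_m, syn_u, syn_m, mixed_m = table
    if unique:
        return syn_u if kinds == {True} else canon_u
    if kinds == {False}:
        return canon_m
    if kinds == {True}:
        return syn_m
    return mixed_m


_EPITHET_CODES = (
    codes.EPITHET_CANONICAL_UNIQUE,
    codes.EPITHET_CANONICAL_MULTIPLE,
    codes.EPITHET_SYNONYM_UNIQUE,
    codes.EPITHET_SYNONYM_MULTIPLE,
    codes.EPITHET_MIXED_MULTIPLE,
)

_WHOLE_CODES = (
    codes.WHOLE_CANONICAL_UNIQUE,
    codes.WHOLE_CANONICAL_MULTIPLE,
    codes.WHOLE_SYNONYM_UNIQUE,
    codes.WHOLE_SYNONYM_MULTIPLE,
    codes.WHOLE_MIXED_MULTIPLE,
)


def _best_by_distance(
    probe: str,
    candidates: Iterable[tuple[str, str, bool]],
    max_d: int,
) -> tuple[list[tuple[str, str, bool]], int] | None:
    """Minimum-distance winners (≤ max_d) among candidate triples."""
    best_d = max_d + 1
    winners: list[tuple[str, str, bool]] = []
    q = probe.casefold()
    for cand, tid, is_syn in candidates:
        d = damerau_levenshtein(q, cand.casefold(), max_d)
        if d < best_d:
            best_d = d
            winners = [(cand, tid, is_syn)]
        elif d == best_d:
            winners.append((cand, tid, is_syn))
    if best_d > max_d:
        return None
    return winners, best_d


def _correction_outcome(
    ref: Reference,
    winners: list[tuple[str, str, bool]],
    distance: int,
    table: tuple[int, ...],
    stage: str,
) -> Outcome:
    ids = sorted({tid for _, tid, _ in winners})
    by_id = {tid: min(cand for cand, t, _ in winners if t == tid) for tid in ids}
    # a taxon counts as a synonym hit only if none of its winning names is canonical
    per_taxon_syn = {
        tid: all(is_syn for _, t, is_syn in winners if t == tid)
        for tid in ids
    }
    kinds = set(per_taxon_syn.values())
    code = _correction_code(kinds, len(ids) == 1, table)
    return _outcome_from_ids(ref, ids, code, by_id[ids[0]], distance, stage)


def correct_epithet(
    query: NameQuery, ref: Reference, max_d: int = 3
) -> Outcome | None:
    """Edit-distance correction within the genus bucket (codes 20–24)."""
    pool = candidate_pool(query.normalized, ref, max_d)
    best = _best_by_distance(query.normalized, pool, max_d)
    if best is None:
        return None
    winners, d = best
    return _correction_outcome(ref, winners, d, _EPITHET_CODES, "epithet-correction")


# ---------------------------------------------------------------------------
# Stage 5b: whole-input correction (declension + whole-string distance)
# ---------------------------------------------------------------------------

def correct_whole(
    query: NameQuery,
    refset: ReferenceSet,
    target: Reference,
    max_d: int = 3,
    config: MapperConfig = DEFAULT_CONFIG,
) -> Outcome | None:
    """Whole-input correction: Latin declension candidates first (codes
    30/31), then whole-string edit distance over the target's names with the
    same length/character pruning (codes 32–36)."""
    # -- declension candidates, exact against the target ---------------------
    cands = [
        c for c in latin_candidates(query.word_blocks, config)
        if c.casefold() != query.normalized.casefold()
    ]
    decl_hits: dict[str, str] = {}
    for cand in cands:
        for tid, _ in target.lookup(cand):
            decl_hits.setdefault(tid, cand)
    if not decl_hits:
        # candidates valid in another reference: resolve into the target via
        # synonym recursion, then lineage-nearest mapping
        matched: list[tuple[Reference, TaxonNode]] = []
        probe_by_node: dict[tuple[str, str], str] = {}
        for ref in refset.others(target.name):
            for cand in cands:
                for tid, _ in ref.lookup(cand):
                    matched.append((ref, ref.nodes[tid]))
                    probe_by_node.setdefault((ref.name, tid), cand)
        if matched:
            rec = recursive_match(matched, target)
            if rec is not None:
                code = (codes.DECLENSION_UNIQUE if len(rec.taxon_ids) == 1
                        else codes.DECLENSION_MULTIPLE)
                return Outcome(code, rec.taxon_ids, rec.matched_name,
                               rec.matched_rank, 0, "declension")
            near = nearest_taxon(matched, target)
            if near is not None:
                return Outcome(codes.DECLENSION_UNIQUE, near.taxon_ids,
                               near.matched_name, near.matched_rank, 0,
                               "declension")
    else:
        ids = sorted(decl_hits)
        code = (codes.DECLENSION_UNIQUE if len(ids) == 1
                else codes.DECLENSION_MULTIPLE)
        return _outcome_from_ids(target, ids, code, decl_hits[ids[0]], 0,
                                 "declension")

    # -- whole-string edit distance over the target's pooled names ----------
    q = query.normalized.casefold()
    qc = Counter(q)
    candidates: list[tuple[str, str, bool]] = []
    for key, entries in target.name_index.items():
        if abs(len(key) - len(q)) > max_d:
            continue
        if _char_profile_diff(qc, Counter(key)) > 2 * max_d:
            continue
        for tid, is_syn in entries:
            node = target.nodes[tid]
            cand = node.canonical_name if not is_syn else next(
                (s for s in node.synonyms if s.casefold() == key), key
            )
            candidates.append((cand, tid, is_syn))
    best = _best_by_distance(query.normalized, candidates, max_d)
    if best is None:
        return None
    winners, d = best
    return _correction_outcome(target, winners, d, _WHOLE_CODES,
                               "whole-correction")


# ---------------------------------------------------------------------------
# Stage 4b: flagged-name nearest mapping
# ---------------------------------------------------------------------------

def _residue_blocks(query: NameQuery, config: MapperConfig) -> list[str]:
    """Leading word-blocks with abbreviations skipped and strain/number
    tokens terminating the scan."""
    out: list[str] = []
    for tok in query.word_blocks:
        low = tok.casefold()
        if low in config.abbreviations or low.rstrip(".") in (
            "sp", "spp", "var", "subsp", "ssp", "cv", "cf", "aff", "f"
        ):
            continue
        if any(ch.isdigit() for ch in tok) or "×" in tok:
            break
        out.append(tok)
        if len(out) == 2:
            break
    return out


def strain_nearest(
    query: NameQuery,
    refset: ReferenceSet,
    target: Reference,
    config: MapperConfig = DEFAULT_CONFIG,
) -> Outcome | None:
    """Nearest mapping for strain-coded / cf. / aff. / genus-only names.

    The abbreviation and strain tokens are stripped; the residual binomial
    (or generic epithet) is matched exactly — in the target first, then via
    other references. Strain-coded names map to the containing species or
    genus (code 40); cf./aff. return a higher taxon within the lineage of
    the match (codes 41/42); '<Genus> sp.' forms map to the genus (code 43).
    """
    residue = " ".join(_residue_blocks(query, config))
    if not residue:
        return None

    probe = make_query(residue, config=config)
    hit = exact_match(probe, target)
    resolved: Outcome | None = hit
    if resolved is None:
        sources = _exact_sources(probe, refset, target.name)
        if sources:
            resolved = recursive_match(sources, target) or nearest_taxon(
                sources, target
            )
    if resolved is None or not resolved.taxon_ids:
        return None

    tid = resolved.taxon_ids[0]
    node = target.nodes[tid]
    if "confer" in query.flags or "affinis" in query.flags:
        code = (codes.CONFER_NEAREST if "confer" in query.flags
                else codes.AFFINIS_NEAREST)
        # higher taxon within the lineage of the match
        if rank_tier(node.rank) == codes.SPECIES_TIER and node.lineage:
            tid = node.lineage[-1]
            node = target.nodes[tid]
    elif "strain_like" in query.flags:
        code = codes.STRAIN_NEAREST
    else:
        code = codes.GENUS_PLACEHOLDER
    return _outcome_from_ids(target, (tid,), code, node.canonical_name, 0,
                             "flagged-nearest")


# ---------------------------------------------------------------------------
# Stage 6: partial mapping
# ---------------------------------------------------------------------------

def partial_map(
    query: NameQuery,
    refset: ReferenceSet,
    target: Reference,
) -> Outcome | None:
    """Exact-match word-block prefixes, longest first (code 100)."""
    blocks = query.word_blocks
    for cut in range(len(blocks) - 1, 0, -1):
        prefix = " ".join(blocks[:cut])
        entries = target.lookup(prefix)
        if entries:
            ids, _ = _resolve_entries(entries)
            out = _outcome_from_ids(target, ids, codes.PARTIAL, prefix, 0,
                                    "partial")
            return out
        probe = make_query(prefix)
        sources = _exact_sources(probe, refset, target.name)
        if sources:
            resolved = recursive_match(sources, target) or nearest_taxon(
                sources, target
            )
            if resolved is not None:
                return Outcome(codes.PARTIAL, resolved.taxon_ids,
                               resolved.matched_name, resolved.matched_rank,
                               0, "partial")
    return None


# ---------------------------------------------------------------------------
# The full cascade
# ---------------------------------------------------------------------------

_FLAGGED = frozenset({"confer", "affinis", "strain_like"})


def _resolve(
    query: NameQuery,
    refset: ReferenceSet,
    target: Reference,
    config: MapperConfig,
) -> Outcome:
    if not query.normalized:
        return Outcome(dropout_code("content-free"), (), stage="dropout")

    hit = exact_match(query, target)
    if hit is not None:
        return hit

    sources = _exact_sources(query, refset, target.name)
    if sources:
        rec = recursive_match(sources, target)
        if rec is not None:
            return rec
        near = nearest_taxon(sources, target)
        if near is not None:
            return near

    kw = query.dropout_keyword()
    if kw is not None:
        return Outcome(dropout_code(kw), (), stage="dropout")
    if "hybrid" in query.flags:
        return Outcome(codes.DROPOUT_HYBRID, (), stage="dropout")

    flagged = bool(query.flags & _FLAGGED)
    genus_only = "genus_only" in query.flags and len(query.word_blocks) > 1
    if flagged or genus_only:
        out = strain_nearest(query, refset, target, config)
        if out is not None:
            return out
        if flagged:  # bypass edit-distance correction entirely
            partial = partial_map(query, refset, target)
            return partial if partial is not None else Outcome(
                codes.UNMAPPED, (), stage="unmapped"
            )

    out = correct_epithet(query, target, config.max_d)
    if out is not None:
        return out
    out = correct_whole(query, refset, target, config.max_d, config)
    if out is not None:
        return out
    partial = partial_map(query, refset, target)
    if partial is not None:
        return partial
    return Outcome(codes.UNMAPPED, (), stage="unmapped")


def map_name(
    raw: str,
    refset: ReferenceSet,
    target: str,
    config: MapperConfig = DEFAULT_CONFIG,
    vmap: Mapping[str, str] | None = None,
    include_others: bool = True,
) -> MappingRecord:
    """Map one raw name string to the target reference.

    Every input yields exactly one record; the record also carries the best
    match found in each other loaded reference when ``include_others``.
    """
    if target not in refset.references:
        raise KeyError(f"target reference {target!r} is not loaded")
    query = make_query(raw, vmap=vmap, config=config)
    outcome = _resolve(query, refset, refset[target], config)
    others: dict[str, Outcome] = {}
    if include_others:
        for ref in refset.others(target):
            others[ref.name] = _resolve(query, refset, ref, config)
    return MappingRecord(
        query=query,
        target=target,
        status_code=outcome.status_code,
        taxon_ids=outcome.taxon_ids,
        matched_name=outcome.matched_name,
        matched_rank=outcome.matched_rank,
        distance=outcome.distance,
        stage=outcome.stage,
        others=others,
    )


def map_names(
    names: Iterable[str],
    refset: ReferenceSet,
    target: str,
    config: MapperConfig = DEFAULT_CONFIG,
    vmap: Mapping[str, str] | None = None,
    include_others: bool = True,
) -> list[MappingRecord]:
    """Batch variant of :func:`map_name`."""
    return [
        map_name(n, refset, target, config=config, vmap=vmap,
                 include_others=include_others)
        for n in names
    ]
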