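"""Cross-reference discrepancy analytics.

Taxonomic checklists disagree: a name canonical in one reference may be a
synonym of something else in another (or even in the same reference), the
same name may be borne by taxa in different domains of life (hemihomonyms),
and the same name may carry different ranks. These scans quantify those
disagreements for any loaded reference set. Names are compared after
case-folding (reference names were already authority-stripped at parse
time).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .codes import rank_tier
from .engine import top_lineage_label
from .reference_io import Reference, ReferenceSet

__all__ = [
    "NameStatusSummary",
    "RankDisagreements",
    "canonical_status_classify",
    "hemihomonym_scan",
    "rank_disagreement_scan",
    "overlap_counts",
    "write_status_report",
]


@dataclass
class NameStatusSummary:
    """Per-name roles across references with the derived classification."""

    name: str
    roles: dict[str, str] = field(default_factory=dict)  # ref -> role
    classification: str = ""  # universal | disputed | unique
    domains: set[str] = field(default_factory=set)
    ranks: set[str] = field(default_factory=set)


def _name_roles(ref: Reference) -> dict[str, set[str]]:
    """Case-folded name -> subset of {'canonical', 'synonym'} in one ref."""
    roles: dict[str, set[str]] = {}
    for node in ref.nodes.values():
        roles.setdefault(node.canonical_name.casefold(), set()).add("canonical")
        for syn in node.synonyms:
            roles.setdefault(syn.casefold(), set()).add("synonym")
    return roles


def canonical_status_classify(
    refset: ReferenceSet,
) -> dict[str, NameStatusSummary]:
    """Classify every canonical name as universal / disputed / unique.

    A canonical name is *disputed* when it also appears as a synonym of some
    other entity anywhere — in another reference or within the same one;
    *universal* when it is canonical in at least two references and never a
    synonym; *unique* when it is canonical in exactly one reference and
    never a synonym. Requires at least two loaded references, since the
    cross-reference classes are undefined otherwise.
    """
    if len(refset) < 2:
        raise ValueError(
            "canonical-status classification needs >= 2 references; "
            "only intra-reference conflicts are defined for a single one"
        )
    per_ref = {ref.name: _name_roles(ref) for ref in refset}
    bearers = _bearers(refset)

    out: dict[str, NameStatusSummary] = {}
    all_names = {n for roles in per_ref.values() for n in roles}
    for name in sorted(all_names):
        roles_here = {rn: roles.get(name, set()) for rn, roles in per_ref.items()}
        canonical_refs = [rn for rn, r in roles_here.items() if "canonical" in r]
        if not canonical_refs:
            continue  # synonym-only names are not classified
        synonym_anywhere = any("synonym" in r for r in roles_here.values())
        if synonym_anywhere:
            cls = "disputed"
        elif len(canonical_refs) >= 2:
            cls = "universal"
        else:
            cls = "unique"
        summary = NameStatusSummary(
            name=name,
            roles={
                rn: ("canonical" if "canonical" in r
                     else "synonym" if "synonym" in r else "absent")
                for rn, r in roles_here.items()
            },
            classification=cls,
        )
        for ref_name, tid in bearers.get(name, []):
            ref = refset[ref_name]
            node = ref.nodes[tid]
            summary.domains.add(top_lineage_label(ref, node))
            summary.ranks.add(node.rank)
        out[name] = summary
    return out


def _bearers(refset: ReferenceSet) -> dict[str, list[tuple[str, str]]]:
    """Case-folded name -> [(reference, taxon_id)] over canonicals + synonyms."""
    bearers: dict[str, list[tuple[str, str]]] = {}
    for ref in refset:
        for key, entries in ref.name_index.items():
            for tid, _ in entries:
                bearers.setdefault(key, []).append((ref.name, tid))
    return bearers


def hemihomonym_scan(refset: ReferenceSet) -> dict[str, set[str]]:
    """Names borne (as canonical or synonym) by taxa in >= 2 distinct
    top-rank lineages, across all references. Order-independent."""
    out: dict[str, set[str]] = {}
    for name, holders in _bearers(refset).items():
        domains = {
            top_lineage_label(refset[rn], refset[rn].nodes[tid])
            for rn, tid in holders
        }
        if len(domains) >= 2:
            out[name] = domains
    return out


@dataclass
class RankDisagreements:
    """Names whose bearers carry >= 2 distinct ranks."""

    within: dict[str, set[str]] = field(default_factory=dict)  # single ref
    across: dict[str, set[str]] = field(default_factory=dict)  # whole set


def rank_disagreement_scan(refset: ReferenceSet) -> RankDisagreements:
    """Report rank disagreements within single references and across the
    whole set separately."""
    result = RankDisagreements()
    per_ref_ranks: dict[str, dict[str, set[str]]] = {}
    for ref in refset:
        ranks: dict[str, set[str]] = {}
        for key, entries in ref.name_index.items():
            for tid, _ in entries:
                ranks.setdefault(key, set()).add(ref.nodes[tid].rank)
        per_ref_ranks[ref.name] = ranks
        for name, rs in ranks.items():
            if len(rs) >= 2:
                result.within.setdefault(name, set()).update(rs)
    union: dict[str, set[str]] = {}
    for ranks in per_ref_ranks.values():
        for name, rs in ranks.items():
            union.setdefault(name, set()).update(rs)
    result.across = {n: rs for n, rs in union.items() if len(rs) >= 2}
    return result


def overlap_counts(refset: ReferenceSet) -> dict[int, int]:
    """Histogram of canonical names by the number of references containing
    them; bucket counts sum to the size of the union."""
    counts: dict[str, int] = {}
    for ref in refset:
        for name in {n.canonical_name.casefold() for n in ref.nodes.values()}:
            counts[name] = counts.get(name, 0) + 1
    hist: dict[int, int] = {}
    for mult in counts.values():
        hist[mult] = hist.get(mult, 0) + 1
    return dict(sorted(hist.items()))


def write_status_report(
    summaries: dict[str, NameStatusSummary], path: str | Path, refset: ReferenceSet
) -> Path:
    """TSV report: one row per name with per-reference roles."""
    path = Path(path)
    ref_names = [r.name for r in refset]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["name", *ref_names, "classification", "domains", "ranks"])
        for name in sorted(summaries):
            s = summaries[name]
            writer.writerow([
                s.name,
                *[s.roles.get(rn, "absent") for rn in ref_names],
                s.classification,
                "|".join(sorted(s.domains)),
                "|".join(sorted(s.ranks)),
            ])
    return path
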