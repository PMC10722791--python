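"""Query normalization and semantic screening.

Raw name strings from occurrence databases and literature arrive with
nomenclatural authorities ("Panax ginseng C.A.Mey."), parenthesized
annotations, strain codes, uncertainty abbreviations (cf., aff.), hybrid
marks, Latin-inflected drug names ("Glycyrrhizae radix") and vernacular
names. Everything here is a pure function of the input string so that a
query's flags are reproducible from the raw text alone.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .config import DEFAULT_CONFIG, MapperConfig

__all__ = [
    "ContentFreeInputError",
    "NameQuery",
    "simple_correct",
    "screen_semantics",
    "latin_candidates",
    "apply_vernacular",
    "load_vernacular_map",
    "make_query",
]


class ContentFreeInputError(ValueError):
    """The input reduces to an empty string after simple correction."""


_PAREN = re.compile(r"\([^()]*\)")
_PUNCT = re.compile(r"[,;:\"“”‘’']+")
_SINGLE_LETTER_ABBREV = re.compile(r"[A-Z]\.")
_YEAR = re.compile(r"(1[789]|20)\d\d")
_CONNECTIVES = {"&", "et", "ex", "and", "in"}


def _is_year(token: str) -> bool:
    return bool(_YEAR.fullmatch(token))


def _authority_like(token: str, index: int) -> bool:
    """Trailing-token authority heuristic.

    A token is treated as authorship if it is a connective, a single-letter
    abbreviation ("L."), or an uppercase-initial purely alphabetic token
    (periods/hyphens/apostrophes allowed) past the second word-block. Tokens
    carrying digits are never authorship here; trailing description years
    are handled separately.
    """
    if token.casefold() in _CONNECTIVES:
        return True
    if _SINGLE_LETTER_ABBREV.fullmatch(token):
        return True
    if index < 2:
        return False
    if any(ch.isdigit() for ch in token):
        return False
    return bool(token[:1].isupper()
                and re.fullmatch(r"[A-Za-z.\-']+", token))


def simple_correct(raw: str, config: MapperConfig = DEFAULT_CONFIG) -> str:
    """Reduce a raw name string to its basic form.

    Removes parenthesized spans, collapses punctuation and whitespace, and
    strips trailing authorship (never touching the first two word-blocks
    except for single-letter abbreviations like "L.").

    Raises :class:`ContentFreeInputError` when nothing remains.
    """
    s = raw.strip()
    if not s:
        raise ContentFreeInputError("empty input")
    while True:
        s2 = _PAREN.sub(" ", s)
        if s2 == s:
            break
        s = s2
    s = s.replace("(", " ").replace(")", " ")
    s = _PUNCT.sub(" ", s)
    tokens = s.split()

    while len(tokens) > 1:
        last = tokens[-1]
        idx = len(tokens) - 1
        if _authority_like(last, idx):
            tokens.pop()
        elif idx >= 2 and _is_year(last):
            tokens.pop()
        else:
            break

    if not tokens:
        raise ContentFreeInputError(f"content-free input: {raw!r}")
    return " ".join(tokens)


def _strip_token(token: str) -> str:
    return token.strip(".,;:!?").casefold()


def screen_semantics(
    normalized: str, config: MapperConfig = DEFAULT_CONFIG
) -> frozenset[str]:
    """Detect semantic markers in a simple-corrected name string.

    Returns flags drawn from ``strain_like``, ``confer``, ``affinis``,
    ``hybrid``, ``dropout:<keyword>``, ``genus_only`` and
    ``declension_candidate``. Pure and total over printable strings.
    """
    flags: set[str] = set()
    tokens = normalized.split()
    if not tokens:
        return frozenset(flags)
    for i, tok in enumerate(tokens):
        low = tok.casefold()
        bare = _strip_token(tok)
        if bare in config.dropout_keywords:
            flags.add(f"dropout:{bare}")
        if "×" in tok or low == "hybrid" or (low == "x" and 0 < i < len(tokens) - 1):
            flags.add("hybrid")
        if low in ("cf", "cf."):
            flags.add("confer")
        if low in ("aff", "aff."):
            flags.add("affinis")
        if any(ch.isdigit() for ch in tok) and not _is_year(tok):
            flags.add("strain_like")
        if bare in config.part_terms:
            flags.add("declension_candidate")
    if len(tokens) == 1 and tokens[0][:1].isupper():
        flags.add("genus_only")
    elif len(tokens) >= 2 and tokens[1].casefold() in ("sp.", "spp.", "sp", "spp"):
        flags.add("genus_only")
    return frozenset(flags)


def _declension_forms(block: str, config: MapperConfig) -> list[str]:
    """Nominative candidates for one word-block (original always first)."""
    forms = [block]
    low = block.casefold()
    for suffix, endings in config.declension:
        if low.endswith(suffix) and len(low) > len(suffix) + 1:
            stem = block[: len(block) - len(suffix)]
            for ending in endings:
                cand = stem + ending
                if cand not in forms:
                    forms.append(cand)
            break  # longest-suffix-first table; apply only one rule
    return forms


def latin_candidates(
    word_blocks: Sequence[str], config: MapperConfig = DEFAULT_CONFIG
) -> list[str]:
    """Expand word-blocks into candidate nominative name strings.

    Materia-medica part terms and conjunctions are removed first; every
    remaining block is expanded through the declension table and the
    per-block candidate sets are combined with ``itertools.product``. The
    part-term-stripped original is always the first candidate. Returns an
    empty list when nothing survives part-term removal.
    """
    kept = [b for b in word_blocks if _strip_token(b) not in config.part_terms]
    if not kept:
        return []
    per_block = [_declension_forms(b, config) for b in kept]
    seen: dict[str, None] = {}
    for combo in itertools.product(*per_block):
        seen.setdefault(" ".join(combo), None)
    return list(seen)


def apply_vernacular(
    raw: str, vmap: Mapping[str, str] | None
) -> tuple[str, bool]:
    """Whole-string vernacular substitution (case-folded lookup)."""
    if not vmap:
        return raw, False
    hit = vmap.get(raw.strip().casefold())
    if hit is None:
        return raw, False
    return hit, True


def load_vernacular_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of (vernacular, scientific name); '#' comments."""
    vmap: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        vmap[parts[0].strip().casefold()] = parts[1].strip()
    return vmap


@dataclass(frozen=True)
class NameQuery:
    """A raw input string with its normalized form and semantic flags."""

    raw: str
    normalized: str
    word_blocks: tuple[str, ...]
    flags: frozenset[str]
    vernacular_applied: bool = False

    @property
    def is_dropout(self) -> bool:
        return any(f.startswith("dropout:") for f in self.flags)

    def dropout_keyword(self) -> str | None:
        for f in sorted(self.flags):
            if f.startswith("dropout:"):
                return f.split(":", 1)[1]
        return None


def make_query(
    raw: str,
    vmap: Mapping[str, str] | None = None,
    config: MapperConfig = DEFAULT_CONFIG,
) -> NameQuery:
    """Build a :class:`NameQuery`: vernacular substitution, simple correction,
    then semantic screening. Content-free inputs yield an empty normalized
    form carrying a ``dropout:content-free`` flag rather than an error, so
    batch mapping is total."""
    substituted, applied = apply_vernacular(raw, vmap)
    try:
        normalized = simple_correct(substituted, config)
    except ContentFreeInputError:
        return NameQuery(
            raw=raw,
            normalized="",
            word_blocks=(),
            flags=frozenset({"dropout:content-free"}),
            vernacular_applied=applied,
        )
    flags = screen_semantics(normalized, config)
    return NameQuery(
        raw=raw,
        normalized=normalized,
        word_blocks=tuple(normalized.split()),
        flags=flags,
        vernacular_applied=applied,
    )
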