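"""Tunable mapper configuration.

All keyword lists, the Latin declension table, and the edit-distance
threshold live here so that deployments can extend them (the defaults cover
the common cases in taxonomic and materia-medica sources but are not
exhaustive).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence, Tuple

#: Genitive suffix -> candidate nominative endings, tried longest-suffix-first.
#: Standard Latin noun declensions (1st: -ae; 2nd: -i/-us/-orum; 3rd: -is).
DEFAULT_DECLENSION: Tuple[Tuple[str, Tuple[str, ...]], ...] = (
    ("orum", ("um", "us")),
    ("arum", ("a",)),
    ("ae", ("a", "e")),
    ("is", ("is", "e", "s")),
    ("us", ("us",)),
    ("i", ("us", "um", "is")),
)


@dataclass(frozen=True)
class MapperConfig:
    """Thresholds and vocabularies used across preprocessing and mapping."""

    #: Maximum accepted edit distance for both correction stages.
    max_d: int = 3
    #: Word-blocks that mark a query as carrying no taxonomic signal of its
    #: own (the embedded species name is typically the host, not the query).
    dropout_keywords: Tuple[str, ...] = (
        "virus",
        "viroid",
        "phytoplasma",
        "endosymbiont",
        "phage",
    )
    #: Latin materia-medica part terms (plant parts etc.) plus conjunctions,
    #: removed before declension expansion.
    part_terms: Tuple[str, ...] = (
        "herba",
        "radix",
        "cortex",
        "folium",
        "flos",
        "fructus",
        "semen",
        "rhizoma",
        "et",
    )
    #: Nomenclatural abbreviations recognised during semantic screening.
    abbreviations: Tuple[str, ...] = (
        "sp.",
        "spp.",
        "var.",
        "subsp.",
        "ssp.",
        "f.",
        "cv.",
        "cf.",
        "aff.",
    )
    declension: Tuple[Tuple[str, Tuple[str, ...]], ...] = DEFAULT_DECLENSION

    def with_extra(
        self,
        *,
        dropout_keywords: Sequence[str] = (),
        part_terms: Sequence[str] = (),
    ) -> "MapperConfig":
        """Return a copy with extra keywords appended (casefolded, deduped)."""
        dk = tuple(dict.fromkeys(
            list(self.dropout_keywords) + [k.casefold() for k in dropout_keywords]
        ))
        pt = tuple(dict.fromkeys(
            list(self.part_terms) + [k.casefold() for k in part_terms]
        ))
        return replace(self, dropout_keywords=dk, part_terms=pt)


DEFAULT_CONFIG = MapperConfig()

_LIST_SPLIT = re.compile(r"[,\s]+")


def load_config(path: str | Path, base: MapperConfig = DEFAULT_CONFIG) -> MapperConfig:
    """Read a ``key = value`` config file extending/overriding the defaults.

    Recognised keys: ``max_d`` (int), ``dropout_keywords``, ``part_terms``
    (comma-separated lists, appended to the defaults). Lines starting with
    '#' are comments; unknown keys raise ``ValueError``.
    """
    kv: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()

    cfg = base
    for key, value in kv.items():
        if key == "max_d":
            cfg = replace(cfg, max_d=int(value))
        elif key == "dropout_keywords":
            cfg = cfg.with_extra(dropout_keywords=_LIST_SPLIT.split(value))
        elif key == "part_terms":
            cfg = cfg.with_extra(part_terms=_LIST_SPLIT.split(value))
        else:
            raise ValueError(f"unknown config key: {key!r}")
    return cfg
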