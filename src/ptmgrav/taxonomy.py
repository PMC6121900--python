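"""PTM class normalization and residue-chemistry grouping.

Modification names arrive as free text from site databases ("*N*6-acetyllysine",
"Glycyl lysine isopeptide (Lys-Gly) (interchain with G-Cter in ubiquitin)").
This module normalizes them to canonical class names and buckets each class
into one of six residue-chemistry groups:

* ``PHOSPHORYLATION`` — phosphoserine / phosphothreonine / phosphotyrosine
* ``LYSINE_N6`` — modifications of the lysine epsilon (N6) amino group
* ``GLY_LYS_ISOPEPTIDE`` — Gly–Lys cross-links, the ubiquitin conjugation mark
* ``SULFUR`` — sulfur-attached chemistry (S-nitrosylation, disulfide, palmitoyl)
* ``OTHER_NITROGEN`` — remaining nitrogen-attached chemistry (N-terminal
  acetylation, N-linked glycosylation, N-myristoylation)
* ``OTHER`` — everything else (O-/C-linked glycans, hydroxylation, ...)

The isopeptide group is kept separate from LYSINE_N6 because the two are
reported as separate percentages; protein-level lysine-N6 statistics can
optionally merge them (see :mod:`ptmgrav.summarize`).

The rule table ships as data (``data/taxonomy.yaml``) so the >80-class
vocabulary of site databases can be extended without touching code. Rules
are ordered and the first match wins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .errors import ValidationError

__all__ = [
    "Group",
    "TaxonomyConfig",
    "PTMClassAssignment",
    "default_taxonomy",
    "normalize_class",
    "assign_group",
    "target_residue",
    "classify",
]


class Group(Enum):
    PHOSPHORYLATION = "PHOSPHORYLATION"
    LYSINE_N6 = "LYSINE_N6"
    OTHER_NITROGEN = "OTHER_NITROGEN"
    SULFUR = "SULFUR"
    GLY_LYS_ISOPEPTIDE = "GLY_LYS_ISOPEPTIDE"
    OTHER = "OTHER"


# typographic italics markup as found in typeset tables: *N*-, *S*-, ...
_MARKUP_RE = re.compile(r"\*")
_INTERCHAIN_RE = re.compile(r"\s*\(interchain with [^)]*\)", re.IGNORECASE)
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class PTMClassAssignment:
    """Normalized class, residue-chemistry group and target residue."""

    raw_modification: str
    canonical_class: str
    group: Group
    target_residue: Optional[str]


@dataclass
class TaxonomyConfig:
    """Ordered pattern->canonical / pattern->group / pattern->residue rules."""

    normalize_rules: Sequence[tuple[re.Pattern, str]]
    canonical_classes: Sequence[str]
    group_rules: Sequence[tuple[re.Pattern, Group]]
    residue_rules: Sequence[tuple[re.Pattern, str]]
    isopeptide_counts_as_n6: bool = False

    _canonical_lookup: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._canonical_lookup = {c.casefold(): c for c in self.canonical_classes}

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "TaxonomyConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "TaxonomyConfig":
        def compile_(p: str) -> re.Pattern:
            return re.compile(p, re.IGNORECASE)

        try:
            norm = [
                (compile_(r["pattern"]), r["canonical"])
                for r in raw.get("normalize", [])
            ]
            canon = list(raw.get("canonical_classes", []))
            groups = [
                (compile_(r["pattern"]), Group[r["group"]])
                for r in raw.get("groups", [])
            ]
            residues = [
                (compile_(r["pattern"]), r["residue"])
                for r in raw.get("target_residues", [])
            ]
        except (KeyError, re.error) as exc:
            raise ValidationError(f"bad taxonomy rule table: {exc}") from exc
        return cls(norm, canon, groups, residues)


@lru_cache(maxsize=1)
def default_taxonomy() -> TaxonomyConfig:
    """The packaged rule table (``data/taxonomy.yaml``)."""
    ref = resources.files("ptmgrav.data") / "taxonomy.yaml"
    with resources.as_file(ref) as p:
        return TaxonomyConfig.from_yaml(p)


def _strip(raw: str) -> str:
    text = _MARKUP_RE.sub("", raw)
    text = _INTERCHAIN_RE.sub("", text)
    return _WS_RE.sub(" ", text).strip()


def normalize_class(raw: str, cfg: Optional[TaxonomyConfig] = None) -> str:
    """Normalize a verbatim modification string to its canonical class name.

    Case-insensitive and idempotent. Typographic markup and cross-link
    partner qualifiers are stripped; chemistry qualifiers such as
    "(Lys-Gly)" or "(GlcNAc)" are preserved, so N-/O-/C-linked glycan
    classes stay distinct. Unknown strings normalize to themselves,
    trimmed and title-cased on the leading word.
    """
    if not raw or not raw.strip():
        raise ValidationError("modification text must be non-empty")
    cfg = cfg or default_taxonomy()
    text = _strip(raw)
    for pattern, canonical in cfg.normalize_rules:
        if pattern.match(text):
            return canonical
    hit = cfg._canonical_lookup.get(text.casefold())
    if hit is not None:
        return hit
    # unknown class: title-style the head, keep any parenthetical verbatim
    head, sep, tail = text.partition("(")
    head = head.strip()
    head = head[:1].upper() + head[1:].lower() if head else head
    return head + (" " + sep + tail if sep else "")


def assign_group(canonical_class: str, cfg: Optional[TaxonomyConfig] = None) -> Group:
    """Map a canonical class into its residue-chemistry group (total; falls
    back to ``Group.OTHER``)."""
    cfg = cfg or default_taxonomy()
    for pattern, group in cfg.group_rules:
        if pattern.search(canonical_class):
            return group
    return Group.OTHER


def target_residue(
    canonical_class: str, cfg: Optional[TaxonomyConfig] = None
) -> Optional[str]:
    """One-letter code of the residue a class chemically targets, or None
    when no unique target exists (e.g. O-linked glycans hit Ser or Thr)."""
    cfg = cfg or default_taxonomy()
    for pattern, residue in cfg.residue_rules:
        if pattern.search(canonical_class):
            return residue
    return None


def classify(raw: str, cfg: Optional[TaxonomyConfig] = None) -> PTMClassAssignment:
    """Normalize + group + target residue in one step."""
    cfg = cfg or default_taxonomy()
    canonical = normalize_class(raw, cfg)
    return PTMClassAssignment(
        raw_modification=raw,
        canonical_class=canonical,
        group=assign_group(canonical, cfg),
        target_residue=target_residue(canonical, cfg),
    )
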