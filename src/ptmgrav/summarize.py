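"""Summary statistics over classified PTM records.

The headline counting rule is *single count per protein per class*: one
protein exhibiting one modification class counts once, no matter how many
sites of that class it carries. Group percentages are shares of these
protein-class pairs (a raw-site-count alternative is available behind a
flag for sensitivity checks). Protein-level lysine-N6 membership is
reported in two modes, since Gly–Lys isopeptide cross-links chemically
attach to the lysine N6 group but are tallied as their own class group:
strict (LYSINE_N6 classes only) and inclusive (plus isopeptide).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .errors import ValidationError
from .ptm_store import PTMRecord
from .selection import SelectionResult
from .taxonomy import Group, PTMClassAssignment, TaxonomyConfig, classify, default_taxonomy

__all__ = [
    "ClassifiedSite",
    "classify_records",
    "count_protein_class_pairs",
    "group_percentages",
    "count_n6_proteins",
    "SummaryReport",
    "build_report",
    "validate_report_dict",
]

ClassifiedSite = tuple[PTMRecord, PTMClassAssignment]


def classify_records(
    records: Sequence[PTMRecord], cfg: Optional[TaxonomyConfig] = None
) -> list[ClassifiedSite]:
    """Attach a class assignment to every site record."""
    cfg = cfg or default_taxonomy()
    return [(r, classify(r.raw_modification, cfg)) for r in records]


def _pairs(classified: Sequence[ClassifiedSite]) -> set[tuple[str, str]]:
    return {(r.accession, a.canonical_class) for r, a in classified}


def count_protein_class_pairs(classified: Sequence[ClassifiedSite]) -> int:
    """|distinct (accession, canonical class)| — the single-count-per-protein rule."""
    return len(_pairs(classified))


def group_percentages(
    classified: Sequence[ClassifiedSite], use_raw_sites: bool = False
) -> dict[Group, float]:
    """Percentage share of each residue-chemistry group, one decimal.

    Shares are over protein-class pairs by default; ``use_raw_sites``
    switches the denominator to raw site records. Groups absent from the
    data report 0.0.
    """
    if not classified:
        raise ValidationError("group percentages are undefined on zero records")
    if use_raw_sites:
        units = [(a.group,) for _, a in classified]
    else:
        by_pair = {(r.accession, a.canonical_class): a.group for r, a in classified}
        units = [(g,) for g in by_pair.values()]
    total = len(units)
    out = {g: 0.0 for g in Group}
    for g in Group:
        n = sum(1 for (u,) in units if u == g)
        out[g] = round(100.0 * n / total, 1)
    return out


def count_n6_proteins(
    classified: Sequence[ClassifiedSite], include_isopeptide: bool = False
) -> int:
    """Distinct proteins carrying >= 1 lysine-N6-group modification.

    ``include_isopeptide`` additionally counts Gly–Lys isopeptide
    (ubiquitin-conjugation) sites as lysine-N6 modifications.
    """
    groups = {Group.LYSINE_N6}
    if include_isopeptide:
        groups.add(Group.GLY_LYS_ISOPEPTIDE)
    return len({r.accession for r, a in classified if a.group in groups})


@dataclass
class SummaryReport:
    """All headline statistics of one pipeline run."""

    n_proteins_selected: int
    n_proteins_with_ptm: int
    n_sites: int
    n_classes: int
    n_protein_class_pairs: int
    group_percentages: dict[Group, float]
    n_proteins_lysine_n6: int
    n_proteins_lysine_n6_incl_isopeptide: int
    fraction_of_detected_proteome: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group_percentages:
            total = sum(self.group_percentages.values())
            if self.n_protein_class_pairs and abs(total - 100.0) > 0.35:
                # one-decimal rounding over six groups can drift by ±0.3
                raise ValidationError(
                    f"group percentages sum to {total}, not ~100"
                )
        if not (
            self.n_proteins_lysine_n6
            <= self.n_proteins_lysine_n6_incl_isopeptide
            <= max(self.n_proteins_with_ptm, self.n_proteins_lysine_n6_incl_isopeptide)
        ):
            raise ValidationError("inconsistent lysine-N6 protein counts")

    def to_dict(self) -> dict:
        return {
            "n_proteins_selected": self.n_proteins_selected,
            "n_proteins_with_ptm": self.n_proteins_with_ptm,
            "n_sites": self.n_sites,
            "n_classes": self.n_classes,
            "n_protein_class_pairs": self.n_protein_class_pairs,
            "group_percentages": {
                g.value: p for g, p in self.group_percentages.items()
            },
            "n_proteins_lysine_n6": self.n_proteins_lysine_n6,
            "n_proteins_lysine_n6_incl_isopeptide": (
                self.n_proteins_lysine_n6_incl_isopeptide
            ),
            "fraction_of_detected_proteome": self.fraction_of_detected_proteome,
        }

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    def to_text(self) -> str:
        lines = [
            f"proteins selected:            {self.n_proteins_selected}",
            f"proteins with >=1 PTM:        {self.n_proteins_with_ptm}",
            f"site records:                 {self.n_sites}",
            f"distinct PTM classes:         {self.n_classes}",
            f"protein-class pairs:          {self.n_protein_class_pairs}",
        ]
        for g in Group:
            lines.append(f"  {g.value:<22} {self.group_percentages.get(g, 0.0):5.1f}%")
        lines.append(
            f"proteins with lysine-N6 mods: {self.n_proteins_lysine_n6}"
            f" (incl. isopeptide: {self.n_proteins_lysine_n6_incl_isopeptide})"
        )
        if self.fraction_of_detected_proteome is not None:
            lines.append(
                f"share of detected proteome:   {self.fraction_of_detected_proteome}%"
            )
        return "\n".join(lines)


def per_protein_class_tally(classified: Sequence[ClassifiedSite]) -> pd.DataFrame:
    """TSV-ready tally: one row per (accession, class) with site count and group."""
    rows: dict[tuple[str, str], dict] = {}
    for r, a in classified:
        key = (r.accession, a.canonical_class)
        if key not in rows:
            rows[key] = {
                "accession": r.accession,
                "canonical_class": a.canonical_class,
                "group": a.group.value,
                "n_sites": 0,
            }
        rows[key]["n_sites"] += 1
    return pd.DataFrame(list(rows.values()))


def build_report(
    selection: SelectionResult,
    classified: Sequence[ClassifiedSite],
    total_detected: Optional[int] = None,
    use_raw_sites: bool = False,
) -> SummaryReport:
    """Assemble the full summary report.

    ``total_detected`` is the size of the upstream detected proteome; when
    given, the selected fraction is reported as a one-decimal percentage.
    """
    if total_detected is not None and total_detected <= 0:
        raise ValidationError("total_detected must be a positive count")
    pairs = _pairs(classified)
    fraction = None
    if total_detected is not None:
        fraction = round(100.0 * len(selection.selected) / total_detected, 1)
    return SummaryReport(
        n_proteins_selected=len(selection.selected),
        n_proteins_with_ptm=len({acc for acc, _ in pairs}),
        n_sites=len(classified),
        n_classes=len({cls for _, cls in pairs}),
        n_protein_class_pairs=len(pairs),
        group_percentages=(
            group_percentages(classified, use_raw_sites)
            if classified
            else {g: 0.0 for g in Group}
        ),
        n_proteins_lysine_n6=count_n6_proteins(classified, False),
        n_proteins_lysine_n6_incl_isopeptide=count_n6_proteins(classified, True),
        fraction_of_detected_proteome=fraction,
    )


_REPORT_KEYS = {
    "n_proteins_selected": int,
    "n_proteins_with_ptm": int,
    "n_sites": int,
    "n_classes": int,
    "n_protein_class_pairs": int,
    "group_percentages": dict,
    "n_proteins_lysine_n6": int,
    "n_proteins_lysine_n6_incl_isopeptide": int,
    "fraction_of_detected_proteome": (int, float, type(None)),
}


def validate_report_dict(data: dict) -> None:
    """Structural check of a serialized report (schema-as-code)."""
    missing = set(_REPORT_KEYS) - set(data)
    if missing:
        raise ValidationError(f"report missing keys: {sorted(missing)}")
    for key, typ in _REPORT_KEYS.items():
        if not isinstance(data[key], typ):
            raise ValidationError(f"report key {key!r} has wrong type")
    bad_groups = set(data["group_percentages"]) - {g.value for g in Group}
    if bad_groups:
        raise ValidationError(f"unknown groups in report: {sorted(bad_groups)}")
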