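"""Differential-accumulation candidate selection.

A protein passes the primary rule when it is detected in spheroid cells
but not in monolayer control cells (zero baseline), or when its spheroid
LfQ is at least ``fold_threshold`` (default 1.8) times the monolayer LfQ.
An optional concordance filter additionally requires up-regulation of the
same protein in a second, independent cell line — by default any strict
up-regulation (ratio > 1, or zero-baseline detection), the weakest reading
consistent with the published worked example, where the second cell line's
ratios dip below 1.8.

This is a deterministic threshold filter, not a statistical test; no
multiple-testing machinery applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .errors import ValidationError
from .proteome_io import ProteinQuant, QuantTable

__all__ = [
    "SelectionCriteria",
    "ProteinRationale",
    "SelectionResult",
    "passes_primary_rule",
    "select_candidates",
]


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds of the selection rule.

    ``fold_threshold`` uses >= at the boundary. ``concordance_fold`` is a
    strict lower bound (ratio must exceed it) on the secondary table.
    ``min_samples_detected`` is an optional detection-count predicate
    applied only when records carry a ``samples_detected`` annotation.
    """

    fold_threshold: float = 1.8
    require_concordance: bool = True
    concordance_fold: float = 1.0
    zero_baseline_passes: bool = True
    min_samples_detected: Optional[int] = None

    def __post_init__(self) -> None:
        if self.fold_threshold <= 0:
            raise ValidationError("fold_threshold must be positive")
        if self.concordance_fold <= 0:
            raise ValidationError("concordance_fold must be positive")


@dataclass(frozen=True)
class ProteinRationale:
    """Why one evaluated protein was selected or rejected."""

    accession: str
    gene_name: str
    rule: Optional[str]  # "zero-baseline" | "fold" | None
    fold_change: Optional[float]
    concordant: Optional[bool]  # None when concordance was not evaluated
    selected: bool
    reason: str


@dataclass
class SelectionResult:
    """Ordered selected accessions plus a rationale for every evaluated protein.

    ``rationale`` is keyed by gene name — the unique key within a quant
    table; accessions can repeat (the published worked table itself
    assigns one accession to two genes). Use :meth:`for_accession` to look
    a rationale up by accession.
    """

    selected: tuple[str, ...]
    rationale: dict[str, ProteinRationale]
    criteria: SelectionCriteria

    def __len__(self) -> int:
        return len(self.selected)

    def for_accession(self, accession: str) -> Optional[ProteinRationale]:
        for r in self.rationale.values():
            if r.accession == accession:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "accession": r.accession,
                "gene": r.gene_name,
                "rule": r.rule or "",
                "fold": "" if r.fold_change is None else round(r.fold_change, 4),
                "concordant": "" if r.concordant is None else r.concordant,
                "selected": r.selected,
                "reason": r.reason,
            }
            for r in self.rationale.values()
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def passes_primary_rule(q: ProteinQuant, c: SelectionCriteria) -> bool:
    """The published selection rule for one protein.

    True iff the protein is undetected at 1g but detected at µg (when
    zero-baseline passing is enabled), or detected at 1g with
    µg/1g >= fold_threshold. A protein undetected under both conditions
    never passes.
    """
    if q.lfq_1g == 0:
        return c.zero_baseline_passes and q.lfq_ug > 0
    return q.lfq_ug / q.lfq_1g >= c.fold_threshold


def _up_regulated(q: ProteinQuant, threshold: float) -> bool:
    # same zero-baseline convention as the primary rule
    if q.lfq_1g == 0:
        return q.lfq_ug > 0
    return q.lfq_ug / q.lfq_1g > threshold


def select_candidates(
    primary: QuantTable,
    secondary: Optional[QuantTable],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> SelectionResult:
    """Apply the selection rule to ``primary``, optionally requiring
    concordant up-regulation in ``secondary``.

    The two tables join on gene name first, falling back to accession.
    A protein that passes the primary rule but is absent from the
    secondary table is excluded with reason "no secondary evidence" —
    this is a rationale entry, not an exception. Selected order follows
    the primary table.
    """
    if criteria.require_concordance:
        if secondary is None:
            raise ValidationError(
                "concordance required but no secondary table given"
            )
        if secondary.cell_line == primary.cell_line:
            raise ValidationError(
                f"primary and secondary tables are both from {primary.cell_line!r}; "
                "concordance needs an independent cell line"
            )
    sec_by_gene = secondary.by_gene() if secondary is not None else {}
    sec_by_acc = secondary.by_accession() if secondary is not None else {}

    selected: list[str] = []
    rationale: dict[str, ProteinRationale] = {}
    for q in primary:
        fold = q.fold_change
        rule: Optional[str] = None
        concordant: Optional[bool] = None
        if passes_primary_rule(q, criteria):
            rule = "zero-baseline" if q.lfq_1g == 0 else "fold"
        if rule is None:
            reason = "fails primary rule"
            is_selected = False
        elif (
            criteria.min_samples_detected is not None
            and q.samples_detected is not None
            and q.samples_detected < criteria.min_samples_detected
        ):
            reason = (
                f"detected in {q.samples_detected} < "
                f"{criteria.min_samples_detected} samples"
            )
            is_selected = False
        elif criteria.require_concordance:
            partner = sec_by_gene.get(q.gene_name) or sec_by_acc.get(q.accession)
            if partner is None:
                concordant = False
                reason = "no secondary evidence"
                is_selected = False
            else:
                concordant = _up_regulated(partner, criteria.concordance_fold)
                is_selected = concordant
                reason = (
                    "selected" if concordant else "not up-regulated in secondary"
                )
        else:
            reason = "selected"
            is_selected = True
        if is_selected:
            selected.append(q.accession)
        rationale[q.gene_name] = ProteinRationale(
            accession=q.accession,
            gene_name=q.gene_name,
            rule=rule,
            fold_change=fold,
            concordant=concordant,
            selected=is_selected,
            reason=reason,
        )
    return SelectionResult(tuple(selected), rationale, criteria)
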