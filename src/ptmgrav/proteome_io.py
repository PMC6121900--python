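"""Two-condition label-free-quantitation (LfQ) protein tables.

A quant table holds one row per protein with its LfQ score in monolayer
cells at normal gravity (``lfq_1g``) and in spheroid cells grown under
simulated microgravity (``lfq_ug``), both on the published x10^8 scale.
A zero score means the protein was not detected under that condition and
is meaningful — it is never treated as missing data.

The 69-protein worked-example tables for the FTC-133 thyroid-cancer and
MCF-7 breast-cancer cell lines ship with the package and are available
through :func:`load_reference_table`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .errors import RowParseError, TableFormatError, ValidationError

__all__ = [
    "ACCESSION_RE",
    "ProteinQuant",
    "QuantTable",
    "ColumnDialect",
    "read_quant_table",
    "write_quant_table",
    "load_reference_table",
    "REFERENCE_CELL_LINES",
]

# 6- or 10-character UniProt accession, first character alphabetic.
ACCESSION_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]{5}(?:[A-Za-z0-9]{4})?$")

REFERENCE_CELL_LINES = ("FTC-133", "MCF-7")
_REFERENCE_FILES = {"FTC-133": "table1_ftc133.tsv", "MCF-7": "table1_mcf7.tsv"}


@dataclass(frozen=True)
class ProteinQuant:
    """One protein's identity plus LfQ scores under the two gravity conditions.

    ``samples_detected`` is an optional detection-count annotation used by
    the optional minimum-sample selection predicate; the reference tables
    do not carry it.
    """

    gene_name: str
    protein_name: str
    accession: str
    lfq_1g: float
    lfq_ug: float
    cell_line: str
    samples_detected: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lfq_1g < 0 or self.lfq_ug < 0:
            raise ValidationError(
                f"{self.gene_name}: LfQ scores must be non-negative "
                f"(got {self.lfq_1g}, {self.lfq_ug})"
            )
        if not ACCESSION_RE.match(self.accession):
            raise ValidationError(
                f"{self.gene_name}: {self.accession!r} is not a UniProt accession"
            )
        if not self.gene_name:
            raise ValidationError("gene_name must be non-empty")

    @property
    def fold_change(self) -> Optional[float]:
        """µg/1g ratio, or None when the protein is undetected at 1g."""
        if self.lfq_1g == 0:
            return None
        return self.lfq_ug / self.lfq_1g


@dataclass
class QuantTable:
    """An ordered collection of :class:`ProteinQuant` from one cell line."""

    records: tuple[ProteinQuant, ...]
    cell_line: str
    provenance: str = ""

    def __post_init__(self) -> None:
        self.records = tuple(self.records)
        bad = [r.gene_name for r in self.records if r.cell_line != self.cell_line]
        if bad:
            raise ValidationError(
                f"records from a different cell line than {self.cell_line!r}: {bad}"
            )
        seen: dict[str, int] = {}
        dups = []
        for r in self.records:
            if r.gene_name in seen:
                dups.append(r.gene_name)
            seen[r.gene_name] = 1
        if dups:
            raise ValidationError(
                f"duplicate (gene, cell_line) entries in {self.cell_line}: "
                + ", ".join(sorted(set(dups)))
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_gene(self) -> dict[str, ProteinQuant]:
        return {r.gene_name: r for r in self.records}

    def by_accession(self) -> dict[str, ProteinQuant]:
        # first occurrence wins; accessions are not guaranteed unique
        out: dict[str, ProteinQuant] = {}
        for r in self.records:
            out.setdefault(r.accession, r)
        return out

    def scaled(self, factor: float) -> "QuantTable":
        """Return a copy with every LfQ score multiplied by ``factor``."""
        if factor <= 0:
            raise ValidationError("scale factor must be positive")
        recs = tuple(
            replace(r, lfq_1g=r.lfq_1g * factor, lfq_ug=r.lfq_ug * factor)
            for r in self.records
        )
        return QuantTable(recs, self.cell_line, self.provenance)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [r.gene_name for r in self.records],
                "protein_name": [r.protein_name for r in self.records],
                "accession": [r.accession for r in self.records],
                "lfq_1g": [r.lfq_1g for r in self.records],
                "lfq_ug": [r.lfq_ug for r in self.records],
            }
        )


@dataclass(frozen=True)
class ColumnDialect:
    """Maps the logical quant-table fields onto file column names."""

    gene: str = "gene"
    protein_name: str = "protein_name"
    accession: str = "accession"
    lfq_1g: str = "lfq_1g"
    lfq_ug: str = "lfq_ug"
    samples_detected: Optional[str] = None

    def required(self) -> tuple[str, ...]:
        return (self.gene, self.protein_name, self.accession, self.lfq_1g, self.lfq_ug)


DEFAULT_DIALECT = ColumnDialect()


def _parse_lfq(raw: str, column: str, row: int) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise RowParseError(row, f"non-numeric LfQ in column {column!r}: {raw!r}")
    if value < 0:
        raise RowParseError(row, f"negative LfQ in column {column!r}: {value}")
    return value


def read_quant_table(
    path: Union[str, Path],
    cell_line: str,
    dialect: ColumnDialect = DEFAULT_DIALECT,
    provenance: str = "",
) -> QuantTable:
    """Read a tab-separated two-condition LfQ table.

    Raises
    ------
    TableFormatError
        when a mandated column is absent, or when any data row fails to
        parse (all row-level problems are reported together, with 1-based
        row numbers).
    ValidationError
        on duplicate (gene, cell_line) pairs or invariant violations.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in dialect.required() if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    records: list[ProteinQuant] = []
    row_errors: list[RowParseError] = []
    for i, values in enumerate(df.to_dict("records"), start=1):
        try:
            samples = None
            if dialect.samples_detected and dialect.samples_detected in df.columns:
                raw = values[dialect.samples_detected]
                samples = int(raw) if str(raw).strip() else None
            records.append(
                ProteinQuant(
                    gene_name=str(values[dialect.gene]).strip(),
                    protein_name=str(values[dialect.protein_name]).strip(),
                    accession=str(values[dialect.accession]).strip(),
                    lfq_1g=_parse_lfq(values[dialect.lfq_1g], dialect.lfq_1g, i),
                    lfq_ug=_parse_lfq(values[dialect.lfq_ug], dialect.lfq_ug, i),
                    cell_line=cell_line,
                    samples_detected=samples,
                )
            )
        except RowParseError as exc:
            row_errors.append(exc)
        except ValidationError as exc:
            row_errors.append(RowParseError(i, str(exc)))
    if row_errors:
        raise TableFormatError(
            f"{path}: {len(row_errors)} unparsable row(s): "
            + "; ".join(str(e) for e in row_errors)
        )
    return QuantTable(tuple(records), cell_line, provenance or str(path))


def write_quant_table(table: QuantTable, path: Union[str, Path]) -> None:
    """Write ``table`` as TSV; LfQ scores serialized at 2 decimal places."""
    path = Path(path)
    lines = ["gene\tprotein_name\taccession\tlfq_1g\tlfq_ug"]
    for r in table.records:
        lines.append(
            f"{r.gene_name}\t{r.protein_name}\t{r.accession}"
            f"\t{r.lfq_1g:.2f}\t{r.lfq_ug:.2f}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_reference_table(cell_line: str) -> QuantTable:
    """Load the packaged 69-protein worked-example table for a cell line.

    ``cell_line`` must be "FTC-133" or "MCF-7".
    """
    if cell_line not in _REFERENCE_FILES:
        raise ValidationError(
            f"no reference table for {cell_line!r}; available: {REFERENCE_CELL_LINES}"
        )
    ref = resources.files("ptmgrav.data") / _REFERENCE_FILES[cell_line]
    with resources.as_file(ref) as p:
        return read_quant_table(p, cell_line, provenance=f"reference:{cell_line}")
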