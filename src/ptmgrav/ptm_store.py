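"""Experimentally verified PTM site records in a flat tab-separated format.

Each record names a UniProt accession, the verbatim modification text, the
1-based residue position and a short sequence window around the site —
conventionally a 9-mer centered on the modified residue, truncated at the
protein termini (so positions 1 and 2 yield 5- and 6-mers). Records whose
window violates that convention are flagged, never discarded: published
site tables do contain the occasional anomalous window, and provenance
must survive parsing.

The five-protein worked-example site table ships with the package
(:func:`load_reference_sites`, 46 rows).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .errors import RowParseError, TableFormatError, ValidationError
from .proteome_io import ACCESSION_RE
from .taxonomy import TaxonomyConfig, classify, default_taxonomy

__all__ = [
    "AMINO_ACIDS",
    "PTMRecord",
    "WindowCheck",
    "PTMDialect",
    "read_ptm_flatfile",
    "write_ptm_flatfile",
    "expected_window",
    "validate_window",
    "read_fasta",
    "load_reference_sites",
]

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: window half-width of the site convention (9-mer = center +/- 4)
_FLANK = 4
_MAX_WINDOW = 2 * _FLANK + 1

KNOWN_SOURCES = frozenset(
    {
        "UniProt",
        "PhosphoSitePlus",
        "SysPTM",
        "dbSNO",
        "MeMo",
        "HPRD",
        "Phospho.ELM",
        "dbPTM",
    }
)


@dataclass(frozen=True)
class PTMRecord:
    """One experimentally verified modification site.

    ``raw_modification`` is kept verbatim; normalization to a canonical
    class happens downstream so provenance is never lost. ``asa`` is the
    accessible surface area covered by the modification in square
    angstroms, when the source provides it.
    """

    accession: str
    raw_modification: str
    position: int
    window: str
    sources: tuple[str, ...] = ()
    pubmed_ids: tuple[int, ...] = ()
    asa: Optional[float] = None

    def __post_init__(self) -> None:
        if not ACCESSION_RE.match(self.accession):
            raise ValidationError(f"{self.accession!r} is not a UniProt accession")
        if not self.raw_modification.strip():
            raise ValidationError("modification text must be non-empty")
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")
        if not self.window:
            raise ValidationError("window must be non-empty")
        bad = set(self.window) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"window {self.window!r} contains non-amino-acid characters: "
                + "".join(sorted(bad))
            )
        if self.asa is not None and self.asa < 0:
            raise ValidationError(f"ASA must be non-negative, got {self.asa}")


@dataclass(frozen=True)
class WindowCheck:
    """Validation flags for one record's sequence window.

    ``chemistry_ok`` is None (indeterminate) when the modification class
    has no unique target residue. ``expected_center_index`` is the 1-based
    index of the modified residue inside a convention-conforming window,
    i.e. ``min(position, 5)``.
    """

    record: PTMRecord
    expected_center_index: int
    center_residue: str
    chemistry_ok: Optional[bool]
    length_ok: bool

    @property
    def ok(self) -> bool:
        """True unless a check failed outright (indeterminate counts as ok)."""
        return self.length_ok and self.chemistry_ok is not False


@dataclass(frozen=True)
class PTMDialect:
    """Maps logical PTM flat-file fields onto column names."""

    accession: str = "accession"
    modification: str = "modification"
    position: str = "position"
    window: str = "window"
    sources: str = "sources"
    pubmed_ids: str = "pubmed_ids"
    asa: str = "asa"

    def required(self) -> tuple[str, ...]:
        return (self.accession, self.modification, self.position, self.window)


DEFAULT_PTM_DIALECT = PTMDialect()


def _split_multi(raw: str) -> tuple[str, ...]:
    return tuple(s.strip() for s in str(raw).split(";") if s.strip())


def read_ptm_flatfile(
    path: Union[str, Path],
    dialect: PTMDialect = DEFAULT_PTM_DIALECT,
    errors: Optional[list] = None,
    warnings: Optional[list] = None,
) -> list[PTMRecord]:
    """Read PTM site records from a dbPTM-style TSV.

    Rows failing hard invariants are collected as :class:`RowParseError`
    into ``errors`` when a list is supplied; otherwise any bad row raises
    :class:`TableFormatError` naming every offending row. Unknown source
    labels are kept verbatim and reported into ``warnings`` when given.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in dialect.required() if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    records: list[PTMRecord] = []
    collected: list[RowParseError] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            try:
                position = int(str(row[dialect.position]).strip())
            except ValueError:
                raise RowParseError(
                    i, f"unparsable position: {row[dialect.position]!r}"
                )
            sources = _split_multi(row.get(dialect.sources, ""))
            for s in sources:
                if s not in KNOWN_SOURCES and warnings is not None:
                    warnings.append(f"row {i}: unknown source label {s!r} (kept)")
            pmids: list[int] = []
            for p in _split_multi(row.get(dialect.pubmed_ids, "")):
                try:
                    pmids.append(int(p))
                except ValueError:
                    raise RowParseError(i, f"unparsable PubMed id: {p!r}")
            asa_raw = str(row.get(dialect.asa, "")).strip()
            try:
                asa = float(asa_raw) if asa_raw else None
            except ValueError:
                raise RowParseError(i, f"unparsable ASA: {asa_raw!r}")
            records.append(
                PTMRecord(
                    accession=str(row[dialect.accession]).strip(),
                    raw_modification=str(row[dialect.modification]).strip(),
                    position=position,
                    window=str(row[dialect.window]).strip(),
                    sources=sources,
                    pubmed_ids=tuple(pmids),
                    asa=asa,
                )
            )
        except RowParseError as exc:
            collected.append(exc)
        except ValidationError as exc:
            collected.append(RowParseError(i, str(exc)))
    if collected:
        if errors is not None:
            errors.extend(collected)
        else:
            raise TableFormatError(
                f"{path}: {len(collected)} bad row(s): "
                + "; ".join(str(e) for e in collected)
            )
    return records


def write_ptm_flatfile(
    records: Sequence[PTMRecord],
    path: Union[str, Path],
    dialect: PTMDialect = DEFAULT_PTM_DIALECT,
) -> None:
    """Write records as a dbPTM-style TSV (inverse of :func:`read_ptm_flatfile`)."""
    path = Path(path)
    header = "\t".join(
        (
            dialect.accession,
            dialect.modification,
            dialect.position,
            dialect.window,
            dialect.sources,
            dialect.pubmed_ids,
            dialect.asa,
        )
    )
    lines = [header]
    for r in records:
        asa = "" if r.asa is None else repr(r.asa)
        lines.append(
            "\t".join(
                (
                    r.accession,
                    r.raw_modification,
                    str(r.position),
                    r.window,
                    ";".join(r.sources),
                    ";".join(str(p) for p in r.pubmed_ids),
                    asa,
                )
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def expected_window(sequence: str, position: int) -> str:
    """Cut the conventional site window from a protein sequence.

    1-based, inclusive: residues ``max(1, position-4) .. min(L, position+4)``.
    The result is 9 residues for interior sites and shorter near the termini
    (never shorter than 5 for sequences of length >= 5).
    """
    length = len(sequence)
    if not 1 <= position <= length:
        raise ValidationError(
            f"position {position} outside sequence of length {length}"
        )
    start = max(1, position - _FLANK)
    end = min(length, position + _FLANK)
    return sequence[start - 1 : end]


def validate_window(
    record: PTMRecord,
    sequence: Optional[str] = None,
    cfg: Optional[TaxonomyConfig] = None,
) -> WindowCheck:
    """Check a record's window against the site convention.

    ``length_ok`` requires window length <= 9 and, when the protein
    sequence is supplied, exact agreement with :func:`expected_window`.
    ``chemistry_ok`` compares the window's center residue (index
    ``min(position, 5)``) with the modification class's target residue;
    it is None when the class has no unique target.
    """
    cfg = cfg or default_taxonomy()
    center_index = min(record.position, _FLANK + 1)
    length_ok = len(record.window) <= _MAX_WINDOW
    if sequence is not None:
        length_ok = length_ok and record.window == expected_window(
            sequence, record.position
        )
    center = (
        record.window[center_index - 1]
        if center_index <= len(record.window)
        else ""
    )
    target = classify(record.raw_modification, cfg).target_residue
    chemistry_ok: Optional[bool] = None if target is None else (center == target)
    return WindowCheck(
        record=record,
        expected_center_index=center_index,
        center_residue=center,
        chemistry_ok=chemistry_ok,
        length_ok=length_ok,
    )


def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Read protein sequences keyed by UniProt accession.

    Accepts both bare-accession headers and UniProt-style
    ``db|ACCESSION|NAME`` headers.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        acc = parts[1] if len(parts) >= 2 and ACCESSION_RE.match(parts[1]) else parts[0]
        sequences[acc] = str(rec.seq).upper()
    return sequences


def load_reference_sites() -> list[PTMRecord]:
    """The packaged five-protein worked-example site table (46 records)."""
    ref = resources.files("ptmgrav.data") / "table2_sites.tsv"
    with resources.as_file(ref) as p:
        return read_ptm_flatfile(p)
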