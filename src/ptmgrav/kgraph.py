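"""Semantic knowledge graph over proteins, quantitation and PTM sites.

Selected proteins, their two-condition LfQ scores and their classified
modification sites are materialized as RDF triples in a small artifact
ontology (one local namespace, no live endpoint). PTM node identity is
the (accession, canonical class, position) tuple, so repeated literature
reports of one site deduplicate — matching the "experimentally verified
site" semantics of aggregated PTM databases.

Querying is by basic graph pattern: a conjunction of triple patterns with
shared variables, evaluated to set semantics. Full SPARQL (OPTIONAL,
aggregation) is out of scope; numeric/string restrictions are applied as
post-hoc filters on binding rows. The matcher orders clauses by an
estimated-selectivity heuristic; correctness is defined against an
exhaustive-enumeration oracle in the test suite.

rdflib provides the triple container and the Turtle / N-Triples
serializations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union
from urllib.parse import quote

from rdflib import Graph, Literal, Namespace, URIRef

from .errors import UsageError, ValidationError
from .proteome_io import QuantTable
from .ptm_store import PTMRecord
from .selection import SelectionResult
from .taxonomy import PTMClassAssignment

__all__ = [
    "PG",
    "ONTOLOGY_PREDICATES",
    "EXTENSION_PREDICATES",
    "register_predicate",
    "Var",
    "GraphPattern",
    "parse_pattern",
    "build_graph",
    "match",
    "apply_filters",
    "serialize",
    "parse_graph",
]

#: artifact-local namespace; accessions embed as PG["P09601"]
PG = Namespace("http://ptmgrav.org/ns#")

ONTOLOGY_PREDICATES = frozenset(
    {
        "hasGene",
        "hasAccession",
        "hasPTM",
        "hasClass",
        "hasGroup",
        "atPosition",
        "hasWindow",
        "hasSource",
        "hasPubMed",
        "lfqAt1g",
        "lfqAtMicroG",
        "selectedBy",
        "inCellLine",
    }
)

# explicitly registered extensions beyond the core ontology
EXTENSION_PREDICATES: set[str] = {
    "hasQuant",
    "hasProteinName",
    "hasASA",
    "reactomePathway",
}


def register_predicate(name: str) -> URIRef:
    """Register an extension predicate and return its IRI."""
    EXTENSION_PREDICATES.add(name)
    return PG[name]


def _pred(name: str) -> URIRef:
    if name not in ONTOLOGY_PREDICATES and name not in EXTENSION_PREDICATES:
        raise ValidationError(
            f"predicate {name!r} is not in the ontology; register it first"
        )
    return PG[name]


def build_graph(
    selection: SelectionResult,
    quant_tables: Sequence[QuantTable],
    classified_records: Sequence[tuple[PTMRecord, PTMClassAssignment]],
    pathway_map: Optional[dict[str, Sequence[str]]] = None,
    warnings: Optional[list] = None,
) -> Graph:
    """Materialize the pipeline state as an RDF graph.

    One protein node per selected accession; one PTM node per
    (accession, canonical class, position); quantitation attached per
    cell line through intermediate quant nodes. Records whose accession
    does not resolve to a selected protein produce a warning entry (when
    ``warnings`` is given) and no triples. ``pathway_map`` optionally
    attaches user-supplied pathway identifiers per accession.
    """
    g = Graph()
    g.bind("pg", PG)
    selected = set(selection.selected)

    for rat in selection.rationale.values():
        if not rat.selected:
            continue
        node = PG[rat.accession]
        g.add((node, _pred("hasAccession"), Literal(rat.accession)))
        g.add((node, _pred("hasGene"), Literal(rat.gene_name)))
        if rat.rule:
            g.add((node, _pred("selectedBy"), Literal(rat.rule)))

    for table in quant_tables:
        for q in table:
            if q.accession not in selected:
                continue
            node = PG[q.accession]
            g.add((node, _pred("hasProteinName"), Literal(q.protein_name)))
            qnode = PG[f"{q.accession}/quant/{quote(table.cell_line, safe='')}"]
            g.add((node, _pred("hasQuant"), qnode))
            g.add((qnode, _pred("inCellLine"), Literal(table.cell_line)))
            g.add((qnode, _pred("lfqAt1g"), Literal(q.lfq_1g)))
            g.add((qnode, _pred("lfqAtMicroG"), Literal(q.lfq_ug)))

    for record, assignment in classified_records:
        if record.accession not in selected:
            if warnings is not None:
                warnings.append(
                    f"PTM record {record.accession}:{record.position} "
                    f"({assignment.canonical_class}) has no selected protein; skipped"
                )
            continue
        pnode = PG[record.accession]
        mnode = PG[
            f"{record.accession}/ptm/"
            f"{quote(assignment.canonical_class, safe='')}/{record.position}"
        ]
        g.add((pnode, _pred("hasPTM"), mnode))
        g.add((mnode, _pred("hasClass"), Literal(assignment.canonical_class)))
        g.add((mnode, _pred("hasGroup"), Literal(assignment.group.value)))
        g.add((mnode, _pred("atPosition"), Literal(record.position)))
        g.add((mnode, _pred("hasWindow"), Literal(record.window)))
        for s in record.sources:
            g.add((mnode, _pred("hasSource"), Literal(s)))
        for p in record.pubmed_ids:
            g.add((mnode, _pred("hasPubMed"), Literal(p)))
        if record.asa is not None:
            g.add((mnode, _pred("hasASA"), Literal(record.asa)))

    for acc, pathways in (pathway_map or {}).items():
        if acc in selected:
            for pw in pathways:
                g.add((PG[acc], _pred("reactomePathway"), Literal(pw)))
    return g


# --------------------------------------------------------------------------
# basic-graph-pattern matching


@dataclass(frozen=True)
class Var:
    """A pattern variable (written ``?name``)."""

    name: str

    def __repr__(self) -> str:  # keeps pattern dumps readable
        return f"?{self.name}"


Term = Union[Var, URIRef, Literal, str, int, float]
Clause = tuple[Term, Term, Term]


@dataclass(frozen=True)
class GraphPattern:
    """A conjunction of triple patterns with shared variables."""

    clauses: tuple[Clause, ...]

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValidationError("a graph pattern needs at least one clause")
        for c in self.clauses:
            if len(c) != 3:
                raise ValidationError(f"clause is not a triple: {c!r}")

    @property
    def variables(self) -> frozenset[str]:
        return frozenset(
            t.name for c in self.clauses for t in c if isinstance(t, Var)
        )


_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<var>\?[A-Za-z_][A-Za-z0-9_]*)
      | (?P<quoted>"(?:[^"\\]|\\.)*")
      | (?P<bare>[^\s]+)
    )""",
    re.VERBOSE,
)


def _parse_term(token: str) -> Term:
    if token.startswith("?"):
        return Var(token[1:])
    if token.startswith('"') and token.endswith('"'):
        return Literal(token[1:-1].replace('\\"', '"'))
    if token.startswith("pg:"):
        return PG[token[3:]]
    if token.startswith("<") and token.endswith(">"):
        return URIRef(token[1:-1])
    try:
        return Literal(int(token))
    except ValueError:
        pass
    try:
        return Literal(float(token))
    except ValueError:
        pass
    # bare word: ontology predicate name or local identifier
    if token in ONTOLOGY_PREDICATES or token in EXTENSION_PREDICATES:
        return PG[token]
    return PG[token]


def parse_pattern(text: str) -> GraphPattern:
    """Parse the minimal one-clause-per-line pattern syntax.

    Terms: ``?var``, ``"string literal"``, bare integers/reals,
    ``pg:Name`` or bare names (both resolve in the artifact namespace),
    ``<full-iri>``. Lines starting with ``#`` are comments; a trailing
    ``.`` per clause is tolerated.
    """
    clauses: list[Clause] = []
    for raw_line in text.splitlines():
        line = raw_line.strip().rstrip(".").strip()
        if not line or line.startswith("#"):
            continue
        tokens = [
            m.group("var") or m.group("quoted") or m.group("bare")
            for m in _TOKEN_RE.finditer(line)
        ]
        if len(tokens) != 3:
            raise ValidationError(
                f"pattern clause must have 3 terms, got {len(tokens)}: {raw_line!r}"
            )
        clauses.append(tuple(_parse_term(t) for t in tokens))  # type: ignore[arg-type]
    return GraphPattern(tuple(clauses))


def _coerce(term: Term) -> Term:
    if isinstance(term, (Var, URIRef, Literal)):
        return term
    return Literal(term)


def _clause_selectivity(
    clause: Clause, graph: list, bound: set[str]
) -> tuple[int, int]:
    """Heuristic sort key: fewer unbound variables first, then fewer
    candidate triples under the currently-bound constants."""
    unbound = sum(
        1 for t in clause if isinstance(t, Var) and t.name not in bound
    )
    candidates = 0
    for triple in graph:
        if all(
            isinstance(p, Var) or p == g for p, g in zip(clause, triple)
        ):
            candidates += 1
    return (unbound, candidates)


def match(
    graph: Iterable[tuple],
    pattern: GraphPattern,
    filters: Optional[Sequence[tuple[str, Callable[[object], bool]]]] = None,
) -> list[dict[str, object]]:
    """Evaluate a basic graph pattern against a triple collection.

    Returns every binding of variables to graph terms under which all
    clauses hold simultaneously, deduplicated to set semantics; the
    result is independent of clause order. A ground pattern that matches
    yields one empty binding. ``filters`` are (variable, predicate) pairs
    applied to the binding rows after matching — the mechanism for range
    or equality restrictions.
    """
    triples = [tuple(t) for t in graph]
    clauses = [tuple(_coerce(t) for t in c) for c in pattern.clauses]

    # order clauses most-selective-first (greedy, re-evaluated as vars bind)
    ordered: list[Clause] = []
    remaining = list(clauses)
    bound: set[str] = set()
    while remaining:
        best = min(remaining, key=lambda c: _clause_selectivity(c, triples, bound))
        remaining.remove(best)
        ordered.append(best)
        bound |= {t.name for t in best if isinstance(t, Var)}

    def extend(binding: dict, clause: Clause):
        for triple in triples:
            new = dict(binding)
            ok = True
            for pat_term, g_term in zip(clause, triple):
                if isinstance(pat_term, Var):
                    if pat_term.name in new:
                        if new[pat_term.name] != g_term:
                            ok = False
                            break
                    else:
                        new[pat_term.name] = g_term
                elif pat_term != g_term:
                    ok = False
                    break
            if ok:
                yield new

    solutions: list[dict] = [{}]
    for clause in ordered:
        solutions = [b for s in solutions for b in extend(s, clause)]
        if not solutions:
            break

    # set semantics
    seen = set()
    unique: list[dict[str, object]] = []
    for s in solutions:
        key = frozenset(s.items())
        if key not in seen:
            seen.add(key)
            unique.append(s)
    if filters:
        unique = apply_filters(unique, filters)
    return unique


def apply_filters(
    rows: Sequence[dict[str, object]],
    filters: Sequence[tuple[str, Callable[[object], bool]]],
) -> list[dict[str, object]]:
    """Keep binding rows satisfying every (variable, predicate) filter.

    Literal values are unwrapped to plain Python before the predicate is
    applied, so filters read naturally (``lambda v: v >= 100``).
    """
    out = []
    for row in rows:
        keep = True
        for var, predicate in filters:
            name = var.lstrip("?")
            if name not in row:
                raise UsageError(f"filter variable ?{name} not bound by pattern")
            value = row[name]
            if isinstance(value, Literal):
                value = value.toPython()
            if not predicate(value):
                keep = False
                break
        if keep:
            out.append(dict(row))
    return out


# --------------------------------------------------------------------------
# serialization

_FORMATS = {"ntriples": "nt", "turtle": "turtle"}


def serialize(graph: Graph, path: Union[str, Path], format: str = "turtle") -> None:
    """Write the graph as N-Triples or Turtle."""
    if format not in _FORMATS:
        raise UsageError(
            f"unknown format {format!r}; expected one of {sorted(_FORMATS)}"
        )
    Path(path).write_text(
        graph.serialize(format=_FORMATS[format]), encoding="utf-8"
    )


def parse_graph(path: Union[str, Path], format: Optional[str] = None) -> Graph:
    """Read a graph back; format inferred from the suffix when omitted."""
    if format is None:
        format = "ntriples" if str(path).endswith(".nt") else "turtle"
    if format not in _FORMATS:
        raise UsageError(
            f"unknown format {format!r}; expected one of {sorted(_FORMATS)}"
        )
    g = Graph()
    g.parse(str(path), format=_FORMATS[format])
    return g
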