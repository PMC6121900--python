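"""Knowledge-graph construction, pattern matching and serialization.

The matcher's correctness oracle is exhaustive enumeration: every
assignment of pattern variables to graph terms is tried against every
clause. Random graphs are drawn over a small vocabulary so enumeration
stays exact.
"""

import itertools
import random

import pytest
from rdflib import Literal, URIRef

from ptmgrav.errors import UsageError, ValidationError
from ptmgrav.kgraph import (
    PG,
    GraphPattern,
    Var,
    apply_filters,
    build_graph,
    match,
    parse_graph,
    parse_pattern,
    serialize,
)


def brute_force_match(triples, pattern):
    """Independent oracle: try every assignment of variables to terms."""
    triples = [tuple(t) for t in triples]
    terms = sorted({t for triple in triples for t in triple}, key=str)
    variables = sorted(pattern.variables)
    solutions = set()
    for combo in itertools.product(terms, repeat=len(variables)):
        binding = dict(zip(variables, combo))

        def resolve(term):
            return binding[term.name] if isinstance(term, Var) else term

        if all(
            tuple(resolve(t) for t in clause) in triples
            for clause in pattern.clauses
        ):
            solutions.add(frozenset(binding.items()))
    return solutions


def as_solution_set(rows):
    return {frozenset(r.items()) for r in rows}


@pytest.fixture(scope="module")
def fixture_graph(reference_selection, ftc_table, mcf_table, classified_sites):
    warnings = []
    g = build_graph(
        reference_selection, [ftc_table, mcf_table], classified_sites,
        warnings=warnings,
    )
    return g, warnings


class TestBuildGraph:
    def test_hmox1_quant_triples(self, fixture_graph):
        g, _ = fixture_graph
        rows = match(
            g,
            parse_pattern(
                'pg:P09601 hasQuant ?q\n'
                '?q inCellLine "FTC-133"\n'
                "?q lfqAt1g ?low\n?q lfqAtMicroG ?high"
            ),
        )
        assert len(rows) == 1
        assert rows[0]["low"].toPython() == pytest.approx(14.62)
        assert rows[0]["high"].toPython() == pytest.approx(108.19)

    def test_unresolvable_accessions_warned_not_raised(self, fixture_graph):
        g, warnings = fixture_graph
        # the printed quant table misassigns GM2A's accession, so its 9
        # site records cannot resolve to a selected protein
        assert len(warnings) == 9
        assert all("P17900" in w for w in warnings)
        assert (PG["P17900"], PG["hasClass"], None) not in g

    def test_empty_records_gives_protein_and_quant_triples_only(
        self, reference_selection, ftc_table
    ):
        g = build_graph(reference_selection, [ftc_table], [])
        assert len(g) > 0
        assert not list(g.triples((None, PG["hasPTM"], None)))

    def test_ptm_nodes_deduplicate_on_class_and_position(
        self, reference_selection, classified_sites
    ):
        # XPOT position 634 carries two different classes -> two PTM nodes;
        # duplicating records adds no triples
        g1 = build_graph(reference_selection, [], classified_sites)
        g2 = build_graph(reference_selection, [], list(classified_sites) * 2)
        assert set(g1) == set(g2)
        nodes_634 = {
            s for s, _, o in g1.triples((None, PG["atPosition"], Literal(634)))
        }
        assert len(nodes_634) == 2

    def test_deterministic_given_identical_inputs(
        self, reference_selection, ftc_table, classified_sites
    ):
        g1 = build_graph(reference_selection, [ftc_table], classified_sites)
        g2 = build_graph(reference_selection, [ftc_table], classified_sites)
        assert set(g1) == set(g2)


class TestMatch:
    def test_phosphoserine_proteins_from_fixture(self, fixture_graph):
        g, _ = fixture_graph
        rows = match(g, parse_pattern('?p hasPTM ?m\n?m hasClass "Phosphoserine"'))
        assert {str(r["p"]) for r in rows} == {str(PG["P25786"])}

    def test_ground_pattern_present_gives_one_empty_binding(self, fixture_graph):
        g, _ = fixture_graph
        rows = match(g, parse_pattern('pg:P09601 hasGene "HMOX1"'))
        assert rows == [{}]

    def test_absent_class_gives_zero_bindings(self, fixture_graph):
        g, _ = fixture_graph
        rows = match(g, parse_pattern('?p hasPTM ?m\n?m hasClass "Nosuchclass"'))
        assert rows == []

    def test_result_invariant_under_clause_permutation(self, fixture_graph):
        g, _ = fixture_graph
        clauses = parse_pattern(
            '?p hasPTM ?m\n?m hasGroup "SULFUR"\n?m atPosition ?pos'
        ).clauses
        results = [
            as_solution_set(match(g, GraphPattern(tuple(perm))))
            for perm in itertools.permutations(clauses)
        ]
        assert all(r == results[0] for r in results)

    def test_unbound_predicate_variable_allowed(self, fixture_graph):
        g, _ = fixture_graph
        rows = match(g, parse_pattern("pg:P25786 ?pred ?obj"))
        preds = {str(r["pred"]) for r in rows}
        assert str(PG["hasGene"]) in preds and str(PG["hasPTM"]) in preds

    def test_pattern_must_have_clauses_and_triples(self):
        with pytest.raises(ValidationError):
            GraphPattern(())
        with pytest.raises(ValidationError):
            parse_pattern("?a ?b\n")

    def test_numeric_range_filter_on_bindings(self, fixture_graph):
        g, _ = fixture_graph
        pattern = parse_pattern("pg:P25786 hasPTM ?m\n?m atPosition ?pos")
        all_rows = match(g, pattern)
        late = match(g, pattern, filters=[("?pos", lambda v: v >= 200)])
        assert {r["pos"].toPython() for r in late} == {208, 211, 243, 256}
        assert len(late) < len(all_rows)

    def test_filter_on_unbound_variable_is_usage_error(self, fixture_graph):
        g, _ = fixture_graph
        with pytest.raises(UsageError):
            match(
                g,
                parse_pattern("pg:P25786 hasPTM ?m"),
                filters=[("?nope", lambda v: True)],
            )


def random_graph_and_pattern(rng):
    """A random graph over a small vocabulary plus a random 1-3 clause
    pattern with up to 3 variables (small terms keep the oracle exact)."""
    subjects = [URIRef(f"urn:s{i}") for i in range(6)]
    predicates = [URIRef(f"urn:p{i}") for i in range(4)]
    objects = [Literal(i) for i in range(10)] + subjects[:4]
    n = rng.randint(5, 200)
    triples = {
        (rng.choice(subjects), rng.choice(predicates), rng.choice(objects))
        for _ in range(n)
    }
    variables = [Var("x"), Var("y"), Var("z")][: rng.randint(1, 3)]
    clauses = []
    for _ in range(rng.randint(1, 3)):
        template = [
            rng.choice(subjects),
            rng.choice(predicates),
            rng.choice(objects),
        ]
        for v in variables:
            if rng.random() < 0.7:
                template[rng.randint(0, 2)] = v
        clauses.append(tuple(template))
    return list(triples), GraphPattern(tuple(clauses))


class TestOracleEquivalence:
    def test_matcher_agrees_with_exhaustive_enumeration(self):
        rng = random.Random(99)
        for _ in range(30):
            triples, pattern = random_graph_and_pattern(rng)
            got = as_solution_set(match(triples, pattern))
            want = brute_force_match(triples, pattern)
            assert got == want

    def test_matcher_agrees_with_rdflib_sparql(self, fixture_graph):
        """Cross-check against an independent SPARQL engine."""
        g, _ = fixture_graph
        rows = match(g, parse_pattern('?p hasPTM ?m\n?m hasGroup "LYSINE_N6"'))
        sparql = g.query(
            "SELECT ?p ?m WHERE { ?p <%s> ?m . ?m <%s> \"LYSINE_N6\" }"
            % (PG["hasPTM"], PG["hasGroup"])
        )
        assert {(r["p"], r["m"]) for r in rows} == {(p, m) for p, m in sparql}


class TestSerialization:
    def test_three_triple_graph_to_ntriples(self, tmp_path):
        from rdflib import Graph

        g = Graph()
        g.add((PG["a"], PG["hasGene"], Literal("X")))
        g.add((PG["a"], PG["atPosition"], Literal(3)))
        g.add((PG["b"], PG["hasGene"], Literal("Y")))
        path = tmp_path / "g.nt"
        serialize(g, path, "ntriples")
        lines = [l for l in path.read_text().splitlines() if l.strip()]
        assert len(lines) == 3
        assert set(parse_graph(path, "ntriples")) == set(g)

    def test_fixture_graph_round_trips_both_formats(self, fixture_graph, tmp_path):
        g, _ = fixture_graph
        for fmt, name in (("turtle", "g.ttl"), ("ntriples", "g.nt")):
            path = tmp_path / name
            serialize(g, path, fmt)
            assert set(parse_graph(path, fmt)) == set(g)

    def test_empty_graph_round_trips(self, tmp_path):
        from rdflib import Graph

        path = tmp_path / "empty.ttl"
        serialize(Graph(), path, "turtle")
        assert len(parse_graph(path, "turtle")) == 0

    def test_unknown_format_is_usage_error(self, fixture_graph, tmp_path):
        g, _ = fixture_graph
        with pytest.raises(UsageError):
            serialize(g, tmp_path / "g.xyz", "rdfxml")
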