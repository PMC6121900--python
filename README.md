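# ptmgrav

When adherent cancer cells are cultured under simulated microgravity (for
example on a random positioning machine), part of the monolayer detaches
and assembles into scaffold-free three-dimensional spheroids. Comparative
label-free-quantitation (LfQ) proteomics of monolayer (1g) versus spheroid
(µg) cells yields per-protein accumulation scores under both conditions;
the proteins that accumulate in spheroids are candidates for driving the
growth-mode transition, and their posttranslational modifications (PTMs)
— phosphorylation, glycosylation, ubiquitination, acetylation — are where
regulation is likely to act.

`ptmgrav` is the in-silico half of such a study, as a tested, reusable
pipeline for proteomics researchers:

1. **Selection** — a protein is a candidate when it is detected in
   spheroids but not in monolayer controls (LfQ₁g = 0, LfQ_µg > 0), or
   accumulates at least 1.8-fold higher (LfQ_µg / LfQ₁g ≥ 1.8); an
   optional concordance filter requires up-regulation of the same protein
   in an independent second cell line.
2. **PTM annotation** — experimentally verified modification sites are
   read from dbPTM-style flat files (accession, modification, 1-based
   position, sequence window, provenance); windows are validated against
   the 9-mer-centered-on-site convention and against the modification's
   target-residue chemistry.
3. **Classification** — verbatim modification texts are normalized to
   canonical classes and grouped by residue chemistry: phosphorylation
   (Ser/Thr/Tyr), lysine-N6 modifications, other nitrogen-attached,
   sulfur-attached, Gly–Lys isopeptide (ubiquitin conjugation), other.
   The rule table is data (`taxonomy.yaml`), not code.
4. **Knowledge graph** — proteins, quantitation, selection rationale and
   classified sites become RDF triples in a small local ontology,
   queryable with basic graph patterns (conjunctive triple patterns with
   variables, plus post-hoc filters) and serializable as Turtle or
   N-Triples.
5. **Summary statistics** — the headline counting rule is *single count
   per protein per class*: a protein exhibiting a class counts once
   regardless of site multiplicity. Group percentages, distinct-class
   counts, lysine-N6 protein membership (with and without isopeptide
   sites) and the selected share of the detected proteome are reported.

A 69-protein two-cell-line worked-example quant table and a 46-row
five-protein PTM site table ship with the package, as does a synthetic
study generator that plants selection outcomes and site classes with an
exact ground-truth ledger.

## Worked example

```
ptmgrav run --demo --out demo_out
```

reads the packaged tables and prints:

```
proteins selected:            69
proteins with >=1 PTM:        5
site records:                 46
distinct PTM classes:         11
protein-class pairs:          15
  PHOSPHORYLATION         13.3%
  LYSINE_N6                6.7%
  OTHER_NITROGEN          33.3%
  SULFUR                  13.3%
  GLY_LYS_ISOPEPTIDE      13.3%
  OTHER                   20.0%
proteins with lysine-N6 mods: 1 (incl. isopeptide: 2)
share of detected proteome:   1.2%
```

All 69 reference proteins pass the selection rule (32 by zero baseline,
37 by fold change) and are concordantly up-regulated in the second cell
line. The five example proteins carry 46 site records that collapse to 15
protein-class pairs; 45 of 46 windows conform to the 9-mer convention
(the one 10-mer is flagged, not dropped). The 69 selected proteins are
1.2% of the 5989 detected. `demo_out/` additionally contains the
selection rationale TSV, the per-protein class tally, the graph in Turtle
and N-Triples, and the JSON report.

Querying the graph:

```
$ cat query.bgp
?p hasPTM ?m
?m hasClass "Phosphoserine"
$ ptmgrav query --graph demo_out/graph.ttl --pattern query.bgp
?m      ?p
http://ptmgrav.org/ns#P25786/ptm/Phosphoserine/14       http://ptmgrav.org/ns#P25786
...
```

Synthetic studies with planted truth:

```
ptmgrav simulate --seed 7 --out sim/      # TSVs + FASTA + ledger.json
ptmgrav run --primary sim/quant_primary.tsv --primary-cell-line SIM-A \
            --secondary sim/quant_secondary.tsv --secondary-cell-line SIM-B \
            --ptm sim/ptm_sites.tsv --out sim_out/
```

The library API mirrors the CLI: `select_candidates`, `read_ptm_flatfile`,
`validate_window`, `classify_records`, `build_graph`, `match`,
`build_report`, `generate_scenario`, `ledger_check`.

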