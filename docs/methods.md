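# Methods

## The selection rule

Let L₁ and Lµ be a protein's LfQ scores (dimensionless, on the ×10⁸
scale the source tables print) in monolayer 1g culture and in spheroids
under simulated microgravity. The primary rule selects a protein iff

    (L₁ = 0 and Lµ > 0)   or   (L₁ > 0 and Lµ / L₁ ≥ τ),   τ = 1.8.

A zero score means "not detected" and is meaningful data, never missing.
A protein undetected under both conditions never passes. The comparison
at the threshold is ≥: the reference table contains a row whose ratio is
1.8297, so either reading would pass every printed row, but ≥ is the
safer interpretation of "τ-fold higher accumulation". The rule is a
deterministic threshold filter; no significance testing or
multiple-testing correction is involved, and none is claimed.

**Concordance filter.** When a second, independent cell line is given,
selection additionally requires up-regulation there. The reference data
show second-line ratios well below 1.8 (e.g. 83.81 → 122.1), so the
filter defaults to the weakest reading consistent with every reference
row: strict up-regulation, Lµ/L₁ > 1.0, with the same zero-baseline
convention. The threshold is configurable (`concordance_fold`). The two
tables join on gene name first (unique within a table) and fall back to
accession; a protein absent from the secondary table is excluded with a
recorded rationale, not an exception.

An optional minimum-detection-count predicate (`min_samples_detected`)
applies only when records carry a `samples_detected` annotation; the
reference tables do not, so it is off by default.

## Site windows

PTM records use 1-based residue positions and a sequence window of up to
9 residues centered on the modified residue, truncated at the protein
termini: window = sequence[max(1, p−4) .. min(L, p+4)]. The center of a
conforming window sits at index min(p, 5). Validation flags (never
drops) records that violate the convention — the packaged reference
table itself contains one 10-mer — and, when the class has a unique
target residue, checks that the window center is that residue. Classes
without a unique target (O-linked glycans attach to Ser or Thr) yield an
*indeterminate* chemistry flag, which does not count as a failure.

## Class taxonomy

Normalization strips typographic markup (`*N*-` → `N-`) and cross-link
partner qualifiers (`(interchain with …)`), preserves chemistry
qualifiers (`(Lys-Gly)`, `(GlcNAc)` — so N-, O- and C-linked glycan
classes stay distinct), folds case to the canonical spelling, and is
idempotent. Unknown strings normalize to themselves, title-styled. One
spelling-variant rule ships with the default table: the reference data's
"N-acetylmelthionine" maps to N-acetylmethionine.

Grouping is by ordered first-match-wins regular expressions over the
canonical name:

| group | rule | examples |
|---|---|---|
| PHOSPHORYLATION | exactly Phospho{serine,threonine,tyrosine} | |
| LYSINE_N6 | `N6-…lysine` | N6-acetyllysine |
| GLY_LYS_ISOPEPTIDE | `Glycyl lysine isopeptide…` | ubiquitin mark |
| SULFUR | `S-…` | S-nitrosocysteine, Cys-Cys |
| OTHER_NITROGEN | remaining `N-…` | N-linked (GlcNAc), N-acetylmethionine |
| OTHER | fallback | O-linked, C-linked, hydroxylation |

Gly–Lys isopeptide chemically modifies the lysine N6 amino group but is
kept as its own group because the two are reported as separate
percentage lines; protein-level lysine-N6 membership is therefore
reported in both strict and isopeptide-inclusive modes rather than
guessing one. PHOSPHORYLATION is deliberately the three S/T/Y classes
(phosphohistidine falls to OTHER unless the user extends the rule). The
whole rule table is YAML data so the >80-class vocabulary of aggregated
PTM databases can be extended without code changes.

## Counting rules

The headline statistic counts **protein-class pairs**: |distinct
(accession, canonical class)|. It is invariant under record duplication
and permutation. Group percentages are pair shares rounded to one
decimal (six rounded shares can sum to 100.0 ± 0.3); a raw-site-count
denominator is available behind `use_raw_sites` for sensitivity
analysis, since pair and site distributions differ whenever proteins
carry several sites of one class. The selected-proteome share is
100 · n_selected / n_detected, one decimal.

## Knowledge graph

One protein node per selected accession (`pg:P09601`); one PTM node per
(accession, canonical class, position), so repeated literature reports
of one site deduplicate; quantitation hangs off per-cell-line quant
nodes. Core predicates: hasGene, hasAccession, hasPTM, hasClass,
hasGroup, atPosition, hasWindow, hasSource, hasPubMed, lfqAt1g,
lfqAtMicroG, selectedBy, inCellLine; registered extensions: hasQuant
(protein → quant node), hasProteinName, hasASA, reactomePathway
(populated only from a user-supplied mapping file — no live database
access anywhere in the core).

Pattern matching implements basic-graph-pattern semantics: all variable
bindings satisfying every clause simultaneously, deduplicated to set
semantics, invariant under clause permutation. The evaluator orders
clauses greedily by (unbound-variable count, candidate-triple count) and
extends bindings clause by clause; the heuristic affects speed only —
correctness is defined by, and tested against, exhaustive enumeration of
all variable-to-term assignments, plus a cross-check against rdflib's
SPARQL engine. OPTIONAL, aggregation and property paths are out of
scope; numeric/string restrictions are post-hoc predicates on binding
rows. Serialization (Turtle, N-Triples) and parsing go through rdflib;
round-trip preserves the triple set exactly.

Records whose accession does not resolve to a selected protein are
reported and skipped, not errors. The packaged demo exercises this
path: the printed quant table assigns the GM2A rows a wrong accession
(P48637, which is glutathione synthetase's), so GM2A's nine site records
cannot resolve and appear as nine warnings.

## Synthetic studies

The generator emulates both input kinds with exact planted truth:

* **Quant tables.** Planted passers either have a zero 1g baseline
  (default fraction 0.46, matching the 32/69 zero-baseline rows of the
  reference table) or a fold drawn uniformly from [1.8, 6.0]; failers
  draw folds from [0.3, 1.75]. Scores are log-normal (µ=1.0, σ=1.4 on
  the log scale), spanning roughly 0.2–600 like the reference table —
  cosmetic only, since selection depends on ratios. All values are
  rounded to the 2-decimal serialization precision *before* the
  pass/fail guarantee is enforced, so planted truth survives file
  round-trips. A concordant secondary table is generated for passers.
* **PTM records.** Sites are planted only on selected proteins (the
  study design annotates the selected set). Classes are drawn from a
  configurable group-frequency distribution (default 0.48 / 0.189 /
  0.128 / 0.04 / 0.034 / 0.129, the published breakdown) and
  instantiated from a per-group class pool in which every class has a
  unique target residue. Sequences are uniform over the 20-letter
  alphabet; each site's center residue is overwritten with the class's
  target, then windows are cut with the standard convention — chemistry
  and window validation hold by construction.
* **Determinism.** One integer seed; per-protein substreams keyed as
  `SeedSequence([seed, index])`, so enlarging a scenario never perturbs
  earlier proteins. Identical scenarios produce byte-identical files.
* **Ledger.** The ground-truth ledger recomputes every summary field
  from its own site lists with independent Counter arithmetic;
  `ledger_check` compares pipeline outputs field-by-field and refuses to
  compare outputs across scenario identifiers.

What the generator does **not** emulate: peptide-level evidence, missing
values other than true zeros, correlated abundances, biological
pathway structure, real PTM co-occurrence patterns, or sequence
composition bias. Passing ledger recovery therefore demonstrates
end-to-end bookkeeping correctness of the pipeline, not performance on
real proteomes.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale: 20 recovery
scenarios of 120 proteins (1–8 sites each), one 3000-protein
frequency-recovery study with one site per protein (so pairs coincide
with sites and recovered percentages estimate the planted frequencies
directly; sampling s.d. ≈ 0.9 points at 48%), 100 random graphs of 5–200
triples over a ~24-term vocabulary (small vocabulary keeps the
exhaustive oracle exact and fast), and 1000 randomized 25-row tables for
the selection property checks. Empirical group frequencies are checked
by chi-square goodness of fit at α = 0.01 on ≥ 5000 sites.

LfQ values serialize at 2 decimal places (the precision of the source
tables); equality after round-trip is exact at that precision. Fold
changes are computed in double precision without rounding.

## Known limitations

* The selection rule reproduces the printed workflow; it cannot recover
  whatever upstream detection-count filtering produced the original
  candidate list from the full detected proteome, because that table is
  not distributed.
* The concordance default ("any strict up-regulation") is a documented
  interpretation of a qualitative statement, not a published threshold.
* The graph query engine is deliberately minimal (conjunctive patterns
  + filters); it is not a SPARQL implementation.
* Live endpoint connectors (UniProt, NCBI) are out of scope; all inputs
  are flat files.
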