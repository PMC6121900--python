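"""Synthetic study generator with planted, ledgered ground truth.

Emulates both pipeline inputs — two-condition LfQ quant tables for a
primary and a secondary cell line, and a flat file of PTM site records
with windows cut from generated protein sequences — so that every stage
(selection, window validation, classification, graph construction,
summary statistics) can be checked against exact planted truth without
any download.

Planting is by construction: planted passers satisfy the selection rule
(zero baseline, or fold >= 1.8 after 2-decimal serialization rounding)
and are up-regulated in the secondary line; planted failers violate the
rule. Site classes are drawn from a configurable residue-chemistry group
frequency distribution; each site's window is cut from the generated
sequence with the standard 9-mer convention after the center residue has
been overwritten with the class's target residue, so chemistry validation
holds by construction.

Randomness: a single integer seed drives per-protein substreams keyed by
protein index (``SeedSequence([seed, index])``), so extending a scenario
with more proteins never perturbs earlier ones.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .errors import UsageError, ValidationError
from .proteome_io import ProteinQuant, QuantTable, write_quant_table
from .ptm_store import PTMRecord, expected_window, write_ptm_flatfile
from .selection import SelectionResult
from .summarize import SummaryReport
from .taxonomy import Group, default_taxonomy, target_residue

__all__ = [
    "CLASS_POOL",
    "DEFAULT_CLASS_FREQUENCY",
    "SyntheticScenario",
    "GroundTruthLedger",
    "ScenarioBundle",
    "generate_scenario",
    "write_scenario",
    "ledger_check",
    "LedgerCheckResult",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# concrete classes drawn per residue-chemistry group; every class here has
# a unique target residue so planted chemistry is checkable
CLASS_POOL: dict[Group, tuple[str, ...]] = {
    Group.PHOSPHORYLATION: ("Phosphoserine", "Phosphothreonine", "Phosphotyrosine"),
    Group.LYSINE_N6: ("N6-acetyllysine", "N6-methyllysine", "N6-succinyllysine"),
    Group.OTHER_NITROGEN: (
        "N-acetylmethionine",
        "N-linked (GlcNAc)",
        "N-myristoyl glycine",
    ),
    Group.SULFUR: (
        "S-nitrosocysteine",
        "S-palmitoyl cysteine",
        "S-cysteinyl 3-(oxidosulfanyl)alanine (Cys-Cys)",
    ),
    Group.GLY_LYS_ISOPEPTIDE: ("Glycyl lysine isopeptide (Lys-Gly)",),
    Group.OTHER: ("C-linked (Man)", "Hydroxyproline"),
}

# group shares of the published summary breakdown; OTHER absorbs the
# remainder so the six shares sum to 1
DEFAULT_CLASS_FREQUENCY: dict[Group, float] = {
    Group.PHOSPHORYLATION: 0.48,
    Group.LYSINE_N6: 0.189,
    Group.OTHER_NITROGEN: 0.128,
    Group.SULFUR: 0.04,
    Group.GLY_LYS_ISOPEPTIDE: 0.034,
    Group.OTHER: 0.129,
}


@dataclass(frozen=True)
class SyntheticScenario:
    """All knobs of one synthetic study.

    Defaults mirror the worked-example study conditions: ~46% of planted
    passers detected only under microgravity (zero baseline), fold changes
    of passers >= 1.8, and site-class frequencies following the published
    group breakdown. The log-normal LfQ parameters span roughly 0.2–600
    on the x10^8 score scale (cosmetic only — selection depends on folds,
    not absolute scores).
    """

    seed: int = 0
    n_proteins: int = 400
    n_selected_planted: int = 40
    lfq_log_mean: float = 1.0
    lfq_log_sd: float = 1.4
    zero_baseline_fraction: float = 0.46
    fold_range_for_passers: tuple[float, float] = (1.8, 6.0)
    fold_range_for_failers: tuple[float, float] = (0.3, 1.75)
    class_frequency: tuple[tuple[Group, float], ...] = tuple(
        DEFAULT_CLASS_FREQUENCY.items()
    )
    sites_per_protein: tuple[int, int] = (1, 10)
    sequence_length: tuple[int, int] = (120, 600)
    primary_cell_line: str = "SIM-A"
    secondary_cell_line: str = "SIM-B"

    def __post_init__(self) -> None:
        if self.n_selected_planted > self.n_proteins:
            raise ValidationError("cannot plant more passers than proteins")
        freq = dict(self.class_frequency)
        if abs(sum(freq.values()) - 1.0) > 1e-9:
            raise ValidationError("class_frequency must sum to 1")
        if self.fold_range_for_passers[0] < 1.8:
            raise ValidationError("passer fold range must start at >= 1.8")
        if self.fold_range_for_failers[1] >= 1.8:
            raise ValidationError("failer fold range must stay below 1.8")
        if not 0.0 <= self.zero_baseline_fraction <= 1.0:
            raise ValidationError("zero_baseline_fraction must be in [0, 1]")
        lo, hi = self.sequence_length
        if lo < 9:
            raise ValidationError(
                "sequences must be at least 9 residues for interior windows"
            )
        if self.sites_per_protein[0] < 0 or self.sites_per_protein[1] < self.sites_per_protein[0]:
            raise ValidationError("bad sites_per_protein range")

    @property
    def scenario_id(self) -> str:
        return (
            f"sim-{self.seed}-{self.n_proteins}-{self.n_selected_planted}-"
            f"{self.sites_per_protein[0]}x{self.sites_per_protein[1]}"
        )


@dataclass(frozen=True)
class PlantedSite:
    accession: str
    canonical_class: str
    group: Group
    position: int


@dataclass
class GroundTruthLedger:
    """Exact planted truth for one scenario; internally recomputable."""

    scenario_id: str
    planted_selected_accessions: tuple[str, ...]
    sites: tuple[PlantedSite, ...]
    expected: dict = field(default_factory=dict)

    def recompute_expected(self, total_detected: Optional[int] = None) -> dict:
        """Tally every summary-report field from the site lists alone.

        Deliberately independent of :mod:`ptmgrav.summarize`: plain
        Counter arithmetic over the planted sites.
        """
        pairs = {(s.accession, s.canonical_class) for s in self.sites}
        pair_groups = {
            (s.accession, s.canonical_class): s.group for s in self.sites
        }
        n_pairs = len(pairs)
        pcts = {}
        for g in Group:
            n = sum(1 for grp in pair_groups.values() if grp == g)
            pcts[g.value] = round(100.0 * n / n_pairs, 1) if n_pairs else 0.0
        n6 = {s.accession for s in self.sites if s.group is Group.LYSINE_N6}
        n6_incl = n6 | {
            s.accession
            for s in self.sites
            if s.group is Group.GLY_LYS_ISOPEPTIDE
        }
        expected = {
            "n_proteins_selected": len(self.planted_selected_accessions),
            "n_proteins_with_ptm": len({s.accession for s in self.sites}),
            "n_sites": len(self.sites),
            "n_classes": len({c for _, c in pairs}),
            "n_protein_class_pairs": n_pairs,
            "group_percentages": pcts,
            "n_proteins_lysine_n6": len(n6),
            "n_proteins_lysine_n6_incl_isopeptide": len(n6_incl),
            "fraction_of_detected_proteome": (
                round(
                    100.0
                    * len(self.planted_selected_accessions)
                    / total_detected,
                    1,
                )
                if total_detected
                else None
            ),
        }
        return expected

    def is_consistent(self) -> bool:
        return self.expected == self.recompute_expected(
            total_detected=self.expected.get("_total_detected")
        ) or self._consistent_ignoring_fraction()

    def _consistent_ignoring_fraction(self) -> bool:
        a = dict(self.expected)
        b = self.recompute_expected()
        a.pop("fraction_of_detected_proteome", None)
        b.pop("fraction_of_detected_proteome", None)
        return a == b


@dataclass
class ScenarioBundle:
    """Everything one synthetic scenario produced."""

    scenario: SyntheticScenario
    quant_primary: QuantTable
    quant_secondary: QuantTable
    ptm_records: tuple[PTMRecord, ...]
    sequences: dict[str, str]
    ledger: GroundTruthLedger


def _round2(x: float) -> float:
    return float(np.round(x, 2))


def _lognormal_lfq(rng: np.random.Generator, s: SyntheticScenario) -> float:
    v = _round2(float(rng.lognormal(s.lfq_log_mean, s.lfq_log_sd)))
    return max(v, 0.1)  # keep denominators away from 0 after rounding


def _passer_quants(
    rng: np.random.Generator, s: SyntheticScenario
) -> tuple[float, float]:
    if rng.random() < s.zero_baseline_fraction:
        return 0.0, _lognormal_lfq(rng, s)
    base = _lognormal_lfq(rng, s)
    fold = rng.uniform(*s.fold_range_for_passers)
    high = _round2(base * fold)
    while high / base < 1.8:  # guard against 2-decimal rounding down
        high = _round2(high + 0.01)
    return base, high


def _failer_quants(
    rng: np.random.Generator, s: SyntheticScenario
) -> tuple[float, float]:
    base = _lognormal_lfq(rng, s)
    fold = rng.uniform(*s.fold_range_for_failers)
    high = _round2(base * fold)
    while base > 0 and high / base >= 1.8:
        high = _round2(high - 0.01)
    return base, max(high, 0.0)


def _secondary_up(rng: np.random.Generator, s: SyntheticScenario) -> tuple[float, float]:
    # concordant: strictly up-regulated (or zero-baseline) in the secondary line
    if rng.random() < s.zero_baseline_fraction / 2:
        return 0.0, _lognormal_lfq(rng, s)
    base = _lognormal_lfq(rng, s)
    high = _round2(base * rng.uniform(1.3, 4.0))
    while high <= base:
        high = _round2(high + 0.01)
    return base, high


def _secondary_any(rng: np.random.Generator, s: SyntheticScenario) -> tuple[float, float]:
    base = _lognormal_lfq(rng, s)
    return base, _round2(base * rng.uniform(0.5, 3.0))


def generate_scenario(s: SyntheticScenario) -> ScenarioBundle:
    """Generate the full synthetic study for one scenario (deterministic)."""
    cfg = default_taxonomy()
    groups, weights = zip(*s.class_frequency)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()

    order_rng = np.random.default_rng(np.random.SeedSequence([s.seed, 2**20]))
    planted_idx = set(
        order_rng.choice(s.n_proteins, size=s.n_selected_planted, replace=False).tolist()
    )

    primary: list[ProteinQuant] = []
    secondary: list[ProteinQuant] = []
    records: list[PTMRecord] = []
    sequences: dict[str, str] = {}
    planted_sites: list[PlantedSite] = []
    planted_accessions: list[str] = []

    for i in range(s.n_proteins):
        rng = np.random.default_rng(np.random.SeedSequence([s.seed, i]))
        accession = f"Q{i:05d}"
        gene = f"SYN{i:04d}"
        name = f"Synthetic protein {i}"
        is_passer = i in planted_idx
        if is_passer:
            lfq_1g, lfq_ug = _passer_quants(rng, s)
            s1g, sug = _secondary_up(rng, s)
            planted_accessions.append(accession)
        else:
            lfq_1g, lfq_ug = _failer_quants(rng, s)
            s1g, sug = _secondary_any(rng, s)
        primary.append(
            ProteinQuant(gene, name, accession, lfq_1g, lfq_ug, s.primary_cell_line)
        )
        secondary.append(
            ProteinQuant(gene, name, accession, s1g, sug, s.secondary_cell_line)
        )

        # sequence + sites only for planted (selected) proteins: the study
        # annotates PTMs on the selected set
        if not is_passer:
            continue
        length = int(rng.integers(s.sequence_length[0], s.sequence_length[1] + 1))
        seq = rng.choice(_AA, size=length)
        n_sites = int(
            rng.integers(s.sites_per_protein[0], s.sites_per_protein[1] + 1)
        )
        n_sites = min(n_sites, length)
        positions = sorted(
            int(p) + 1
            for p in rng.choice(length, size=n_sites, replace=False)
        )
        site_groups = rng.choice(len(groups), size=n_sites, p=weights)
        chosen: list[tuple[int, str, Group]] = []
        for pos, gi in zip(positions, site_groups):
            group = groups[int(gi)]
            pool = CLASS_POOL[group]
            cls = pool[int(rng.integers(len(pool)))]
            res = target_residue(cls, cfg)
            seq[pos - 1] = res  # chemistry holds by construction
            chosen.append((pos, cls, group))
        seq_str = "".join(seq.tolist())
        sequences[accession] = seq_str
        for pos, cls, group in chosen:
            records.append(
                PTMRecord(
                    accession=accession,
                    raw_modification=cls,
                    position=pos,
                    window=expected_window(seq_str, pos),
                    sources=("dbPTM",),
                    pubmed_ids=(10_000_000 + i,),
                )
            )
            planted_sites.append(PlantedSite(accession, cls, group, pos))

    ledger = GroundTruthLedger(
        scenario_id=s.scenario_id,
        planted_selected_accessions=tuple(planted_accessions),
        sites=tuple(planted_sites),
    )
    ledger.expected = ledger.recompute_expected()
    return ScenarioBundle(
        scenario=s,
        quant_primary=QuantTable(
            tuple(primary), s.primary_cell_line, provenance=s.scenario_id
        ),
        quant_secondary=QuantTable(
            tuple(secondary), s.secondary_cell_line, provenance=s.scenario_id
        ),
        ptm_records=tuple(records),
        sequences=sequences,
        ledger=ledger,
    )


def write_scenario(bundle: ScenarioBundle, out_dir: Union[str, Path]) -> None:
    """Materialize a scenario as TSV + FASTA + a JSON ledger."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_quant_table(bundle.quant_primary, out / "quant_primary.tsv")
    write_quant_table(bundle.quant_secondary, out / "quant_secondary.tsv")
    write_ptm_flatfile(bundle.ptm_records, out / "ptm_sites.tsv")
    with open(out / "sequences.fasta", "w", encoding="utf-8") as fh:
        for acc, seq in bundle.sequences.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    ledger_dict = {
        "scenario_id": bundle.ledger.scenario_id,
        "planted_selected_accessions": list(
            bundle.ledger.planted_selected_accessions
        ),
        "sites": [
            {
                "accession": st.accession,
                "canonical_class": st.canonical_class,
                "group": st.group.value,
                "position": st.position,
            }
            for st in bundle.ledger.sites
        ],
        "expected": bundle.ledger.expected,
    }
    (out / "ledger.json").write_text(
        json.dumps(ledger_dict, indent=2) + "\n", encoding="utf-8"
    )


@dataclass
class LedgerCheckResult:
    passed: bool
    diffs: dict[str, tuple]

    def __bool__(self) -> bool:
        return self.passed


def ledger_check(
    report: SummaryReport,
    selection: SelectionResult,
    ledger: GroundTruthLedger,
    scenario_id: Optional[str] = None,
) -> LedgerCheckResult:
    """Compare pipeline outputs with planted truth, field by field.

    Passes iff the selected set equals the planted set and every summary
    field matches the ledger exactly. A wrong ``scenario_id`` is a usage
    error — comparing outputs across scenarios is meaningless.
    """
    if scenario_id is not None and scenario_id != ledger.scenario_id:
        raise UsageError(
            f"scenario id mismatch: outputs from {scenario_id!r}, "
            f"ledger from {ledger.scenario_id!r}"
        )
    diffs: dict[str, tuple] = {}
    got_sel = tuple(sorted(selection.selected))
    want_sel = tuple(sorted(ledger.planted_selected_accessions))
    if got_sel != want_sel:
        diffs["selected_accessions"] = (got_sel, want_sel)
    got = report.to_dict()
    for key, want in ledger.expected.items():
        if key == "fraction_of_detected_proteome" and want is None:
            continue
        if got.get(key) != want:
            diffs[key] = (got.get(key), want)
    return LedgerCheckResult(passed=not diffs, diffs=diffs)
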