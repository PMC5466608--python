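"""Per-gene and per-group carrier and allele-count bookkeeping.

Only P/LP calls count as mutations. Carriers are assumed heterozygous,
so each carrier contributes one alternate allele; a gene's case allele
count (AC) for case-control testing then excludes carriers whose event
was a CNV (not allele-countable against an SNV/indel control table) and
double carriers (mutations in two different genes), i.e.

    case_AC = n_carriers - |CNV carriers  U  double carriers|  (per gene)

Per-gene counts include double carriers in both genes; the overall
carrier total counts each woman once. Named low-risk alleles and
monoallelic MUTYH are tracked separately from the breast-cancer-gene
totals. The case allele number (AN) is ``2 x cohort - excluded
alleles``; by default one allele is removed per CNV-carrying case, the
only reading of the study's bookkeeping consistent with its printed AN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .classify import Classification, is_mutation
from .cnv import CnvCall
from .cohort_io import VariantRecord
from .panel import PanelConfig, RISK_GROUPS

log = logging.getLogger(__name__)

MUTATION_TYPES = ("indel_nonsense", "splicing", "missense", "cnv", "other")

_CONSEQ_TO_TYPE = {
    "nonsense": "indel_nonsense", "frameshift": "indel_nonsense",
    "splice_site": "splicing", "missense": "missense",
    "whole_gene_deletion": "cnv",
    "intronic": "other", "synonymous": "other", "other_noncoding": "other",
}
TRUNCATING_TYPES = frozenset({"indel_nonsense", "splicing"})


@dataclass
class GeneTally:
    gene: str
    n_carriers: int = 0
    type_breakdown: dict[str, int] = field(
        default_factory=lambda: {t: 0 for t in MUTATION_TYPES})
    n_double_carriers: int = 0
    n_cnv_carriers: int = 0
    case_ac: int = 0
    case_an: int = 0

    @property
    def n_mutations(self) -> int:
        return sum(self.type_breakdown.values())


@dataclass
class GroupTally:
    group: str
    n_carriers: int  # carrier slots summed over member genes (as printed)
    rate: float      # n_carriers / cohort size


@dataclass
class CohortSummary:
    cohort_size: int
    n_unique_carriers: int
    n_double_carriers: int
    n_mutations: int
    double_carrier_pairs: list[tuple[str, tuple[str, str]]]
    n_low_risk_carriers: int
    carrier_rate: float
    carrier_rate_excl_mutyh: float


def derive_case_AN(cohort_size: int, excluded_alleles: int = 0) -> int:
    """Case allele number: 2 x cohort minus excluded alleles."""
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    an = 2 * cohort_size - excluded_alleles
    if an < 0:
        raise ValueError("excluded alleles exceed total alleles")
    return an


def tally_carriers(
    variant_calls: Iterable[tuple[VariantRecord, Classification]],
    cnv_calls: Iterable[tuple[CnvCall, Classification]],
    panel: PanelConfig,
    cohort_size: int,
    an_exclusions: int | None = None,
    truncating_subset_genes: Iterable[str] = ("CHEK2",),
) -> tuple[list[GeneTally], list[GroupTally], CohortSummary]:
    """Aggregate final classifications into spectrum and allele tallies.

    ``an_exclusions`` overrides the excluded-allele count for the case
    AN; the default (None) removes one allele per CNV-carrying case.
    For each gene in ``truncating_subset_genes`` an extra ``<GENE>_trunc``
    tally restricted to indel/nonsense and splicing mutations is
    emitted (the subset used when a gene's missense burden is not
    case-control comparable).
    """
    variant_calls = list(variant_calls)
    cnv_calls = list(cnv_calls)

    seen_keys: set[tuple[str, str]] = set()
    for rec, _ in variant_calls:
        key = (rec.sample_id, rec.variant_key)
        if key in seen_keys:
            raise ValueError(f"duplicate sample-variant key {key}")
        seen_keys.add(key)

    # per gene: carrier sets and mutation-type events
    carriers: dict[str, set[str]] = {g: set() for g in panel.genes}
    trunc_carriers: dict[str, set[str]] = {g: set() for g in panel.genes}
    cnv_carriers: dict[str, set[str]] = {g: set() for g in panel.genes}
    breakdown: dict[str, dict[str, int]] = {
        g: {t: 0 for t in MUTATION_TYPES} for g in panel.genes}
    genes_of_sample: dict[str, set[str]] = {}
    low_risk_carriers: set[str] = set()
    homozygous_warned = 0

    for rec, call in variant_calls:
        if call.label == "LOW_RISK":
            low_risk_carriers.add(rec.sample_id)
            continue
        if not is_mutation(call.label):
            continue
        if rec.gene not in panel:
            raise ValueError(f"mutation in non-panel gene {rec.gene!r}")
        mtype = _CONSEQ_TO_TYPE.get(rec.consequence, "other")
        if rec.allelic_ratio is not None and rec.allelic_ratio > 0.95:
            homozygous_warned += 1  # contributes 2 alleles, flagged below
        carriers[rec.gene].add(rec.sample_id)
        if mtype in TRUNCATING_TYPES:
            trunc_carriers[rec.gene].add(rec.sample_id)
        breakdown[rec.gene][mtype] += 1
        genes_of_sample.setdefault(rec.sample_id, set()).add(rec.gene)

    if homozygous_warned:
        log.warning("%d apparent homozygous carrier call(s); carriers are "
                    "modeled heterozygous", homozygous_warned)

    all_cnv_samples: set[str] = set()
    for cnv, call in cnv_calls:
        all_cnv_samples.add(cnv.sample_id)  # AN bookkeeping counts all CNV cases
        if not is_mutation(call.label):
            continue
        if cnv.gene not in panel:
            raise ValueError(f"CNV in non-panel gene {cnv.gene!r}")
        carriers[cnv.gene].add(cnv.sample_id)
        cnv_carriers[cnv.gene].add(cnv.sample_id)
        breakdown[cnv.gene]["cnv"] += 1
        genes_of_sample.setdefault(cnv.sample_id, set()).add(cnv.gene)

    double_samples = {s for s, gs in genes_of_sample.items() if len(gs) >= 2}
    if an_exclusions is None:
        an_exclusions = len(all_cnv_samples)
    case_an = derive_case_AN(cohort_size, an_exclusions)

    gene_tallies: list[GeneTally] = []
    for g in panel.genes:
        cs = carriers[g]
        doubles = cs & double_samples
        excluded = cnv_carriers[g] | doubles
        gene_tallies.append(GeneTally(
            gene=g, n_carriers=len(cs), type_breakdown=breakdown[g],
            n_double_carriers=len(doubles),
            n_cnv_carriers=len(cnv_carriers[g]),
            case_ac=len(cs) - len(excluded), case_an=case_an))

    for g in truncating_subset_genes:
        if g not in panel:
            continue
        tc = trunc_carriers[g]
        doubles = tc & double_samples
        sub_breakdown = {t: (breakdown[g][t] if t in TRUNCATING_TYPES else 0)
                         for t in MUTATION_TYPES}
        gene_tallies.append(GeneTally(
            gene=f"{g}_trunc", n_carriers=len(tc),
            type_breakdown=sub_breakdown, n_double_carriers=len(doubles),
            n_cnv_carriers=0, case_ac=len(tc) - len(doubles),
            case_an=case_an))

    group_tallies = []
    for grp in RISK_GROUPS:
        n = sum(len(carriers[g]) for g in panel.genes_in_group(grp))
        group_tallies.append(GroupTally(grp, n, n / cohort_size))

    unique = set().union(*carriers.values()) if carriers else set()
    n_mut = sum(t.n_mutations for t in gene_tallies
                if not t.gene.endswith("_trunc"))
    mutyh_carriers = carriers.get("MUTYH", set())
    excl_mutyh = unique - (mutyh_carriers -
                           {s for s, gs in genes_of_sample.items()
                            if gs - {"MUTYH"}})
    pairs = sorted((s, tuple(sorted(genes_of_sample[s])))
                   for s in double_samples)
    summary = CohortSummary(
        cohort_size=cohort_size,
        n_unique_carriers=len(unique),
        n_double_carriers=len(double_samples),
        n_mutations=n_mut,
        double_carrier_pairs=[(s, (gs[0], gs[1])) for s, gs in pairs],
        n_low_risk_carriers=len(low_risk_carriers),
        carrier_rate=len(unique) / cohort_size,
        carrier_rate_excl_mutyh=len(excl_mutyh) / cohort_size,
    )
    return gene_tallies, group_tallies, summary


def write_gene_tallies(tallies: Iterable[GeneTally], cohort_size: int,
                       path: str | Path) -> None:
    """Mutation-spectrum TSV (gene, n, %, I/N, S, M, C, O, doubles, AC, AN)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tn\tpct\tindel_nonsense\tsplicing\tmissense\tcnv\t"
                 "other\tn_double\tcase_ac\tcase_an\n")
        for t in tallies:
            b = t.type_breakdown
            fh.write("\t".join([
                t.gene, str(t.n_carriers),
                f"{100 * t.n_carriers / cohort_size:.2f}",
                str(b["indel_nonsense"]), str(b["splicing"]),
                str(b["missense"]), str(b["cnv"]), str(b["other"]),
                str(t.n_double_carriers), str(t.case_ac), str(t.case_an),
            ]) + "\n")


def tallies_by_gene(tallies: Iterable[GeneTally]) -> Mapping[str, GeneTally]:
    return {t.gene: t for t in tallies}
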