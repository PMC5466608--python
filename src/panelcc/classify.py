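"""Rule-based germline variant classification.

Variants get one of five pathogenicity tiers (P, LP, VUS, LB, B) or two
bookkeeping buckets: LOW_RISK for named low-penetrance alleles, and
EXCLUDED for variants too common in any reference population to be a
high-penetrance mutation. The engine is a deterministic composition:

1. named low-risk alleles (absorbing);
2. the population-allele-frequency gate — any source AF above
   ``af_exclusion`` (default 3%) excludes the variant outright; any
   source AF above ``af_pathogenic_ceiling`` (default 0.3%) caps the
   label at VUS/LB/B; named exception variants (by default
   CHEK2 c.1100delC, a common pathogenic founder allele) bypass both;
3. the loss-of-function rule — nonsense, frameshift, whole-gene
   deletion, or canonical +/-1/2 splice variants are LP, unless the
   position lies beyond a configured benign-truncation boundary;
4. ClinVar concordance — missense, deeper-splice, intronic or
   synonymous variants asserted P/LP by at least ``min_concordant``
   trusted submitters (per-gene override: TP53 needs only one) are LP;
5. symmetric benign concordance — at least two trusted submitters
   asserting B/LB with no P/LP assertion gives LB (B when every such
   assertion is B);
6. otherwise VUS.

Every consulted rule is appended to ``rule_trace``. A second,
independently produced classification (an ACMG-style engine run
supplied as input) is merged by :func:`resolve_consensus`: concordant
calls are final, discordant calls keep the primary label but are
flagged for expert review.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .cohort_io import VariantRecord

LABELS = ("P", "LP", "VUS", "LB", "B", "LOW_RISK", "EXCLUDED")
MUTATION_LABELS = frozenset({"P", "LP"})

# af_gate outcomes
EXCLUDED = "EXCLUDED"
PATH_ELIGIBLE = "PATH_ELIGIBLE"
VUS_CEILING = "VUS_CEILING"

LOF_CONSEQUENCES = frozenset({"nonsense", "frameshift", "whole_gene_deletion"})
CLINVAR_RULE_CONSEQUENCES = frozenset(
    {"missense", "splice_site", "intronic", "synonymous"})


def is_mutation(label: str) -> bool:
    """P and LP are counted identically downstream."""
    return label in MUTATION_LABELS


@dataclass
class Classification:
    label: str
    rule_trace: list[str] = field(default_factory=list)
    review_flag: bool = False

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass
class ClassifierConfig:
    af_exclusion: float = 0.03
    af_pathogenic_ceiling: float = 0.003
    exception_variants: frozenset[str] = frozenset({"CHEK2 c.1100delC"})
    lof_consequences: frozenset[str] = LOF_CONSEQUENCES
    lof_splice_offsets: frozenset[int] = frozenset({-2, -1, 1, 2})
    trusted_submitters: frozenset[str] = frozenset({
        "Ambry", "Sharing Clinical Reports Project", "InVitae", "GeneDX",
        "Emory", "InSiGHT"})
    min_concordant: int = 2
    min_concordant_override: Mapping[str, int] = field(
        default_factory=lambda: {"TP53": 1})
    low_risk_alleles: frozenset[str] = frozenset(
        {"CHEK2 p.I157T", "CHEK2 p.S428F"})
    benign_truncation_boundaries: Mapping[str, int] = field(
        default_factory=dict)
    # exon lengths per gene, used for CNV frame arithmetic
    exon_lengths: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.af_pathogenic_ceiling > self.af_exclusion:
            raise ValueError("af_pathogenic_ceiling must be <= af_exclusion")
        if self.min_concordant < 1:
            raise ValueError("min_concordant must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        for k in ("exception_variants", "lof_consequences",
                  "lof_splice_offsets", "trusted_submitters",
                  "low_risk_alleles"):
            d[k] = sorted(d[k])
        d["min_concordant_override"] = dict(self.min_concordant_override)
        d["benign_truncation_boundaries"] = dict(
            self.benign_truncation_boundaries)
        d["exon_lengths"] = {g: list(v) for g, v in self.exon_lengths.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassifierConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("exception_variants", "lof_consequences",
                  "lof_splice_offsets", "trusted_submitters",
                  "low_risk_alleles"):
            if k in d:
                d[k] = frozenset(d[k])
        if "exon_lengths" in d:
            d["exon_lengths"] = {g: tuple(v)
                                 for g, v in d["exon_lengths"].items()}
        return cls(**d)


def _named_keys(record: VariantRecord) -> set[str]:
    keys = set()
    if record.hgvs_c:
        keys.add(f"{record.gene} {record.hgvs_c}")
    if record.hgvs_p:
        keys.add(f"{record.gene} {record.hgvs_p}")
    return keys


def af_gate(record: VariantRecord,
            cfg: ClassifierConfig | None = None) -> str:
    """Population-frequency gate; absent AF sources count as zero."""
    cfg = cfg or ClassifierConfig()
    if _named_keys(record) & cfg.exception_variants:
        return PATH_ELIGIBLE
    afs = record.pop_af.values()
    if any(af > cfg.af_exclusion for af in afs):
        return EXCLUDED
    if any(af > cfg.af_pathogenic_ceiling for af in afs):
        return VUS_CEILING
    return PATH_ELIGIBLE


def rule_lof(record: VariantRecord,
             cfg: ClassifierConfig | None = None) -> str | None:
    """Loss-of-function rule; returns 'LP' or None (no call)."""
    cfg = cfg or ClassifierConfig()
    is_lof = record.consequence in cfg.lof_consequences or (
        record.consequence == "splice_site"
        and record.splice_offset in cfg.lof_splice_offsets)
    if not is_lof:
        return None
    boundary = cfg.benign_truncation_boundaries.get(record.gene)
    if boundary is not None and record.pos > boundary:
        return None  # truncation after a known benign truncating variant
    return "LP"


def _concordant_assertions(record: VariantRecord, cfg: ClassifierConfig,
                           wanted: frozenset[str]) -> int:
    # one vote per trusted submitter; a submitter asserting twice counts once
    return len({sub for sub, a in record.clinvar
                if sub in cfg.trusted_submitters and a in wanted})


def rule_clinvar_concordance(record: VariantRecord,
                             cfg: ClassifierConfig | None = None,
                             ) -> str | None:
    """Trusted-submitter P/LP concordance for non-LoF consequences."""
    cfg = cfg or ClassifierConfig()
    if record.consequence not in CLINVAR_RULE_CONSEQUENCES:
        return None
    if (record.consequence == "splice_site" and record.splice_offset is not None
            and abs(record.splice_offset) < 3):
        return None  # canonical-site territory belongs to the LoF rule
    need = cfg.min_concordant_override.get(record.gene, cfg.min_concordant)
    if _concordant_assertions(record, cfg, frozenset({"P", "LP"})) >= need:
        return "LP"
    return None


def _benign_call(record: VariantRecord, cfg: ClassifierConfig) -> str | None:
    if _concordant_assertions(record, cfg, frozenset({"P", "LP"})) > 0:
        return None
    n_benign = _concordant_assertions(record, cfg, frozenset({"B", "LB"}))
    if n_benign < 2:
        return None
    only_b = _concordant_assertions(record, cfg, frozenset({"LB"})) == 0
    return "B" if only_b else "LB"


def classify(record: VariantRecord,
             cfg: ClassifierConfig | None = None) -> Classification:
    """Full single-variant classification with a rule trace."""
    cfg = cfg or ClassifierConfig()
    trace: list[str] = []
    if _named_keys(record) & cfg.low_risk_alleles:
        trace.append("low_risk_allele")
        return Classification("LOW_RISK", trace)
    if record.consequence is None:
        trace.append("missing_consequence")
        return Classification("VUS", trace, review_flag=True)
    gate = af_gate(record, cfg)
    trace.append(f"af_gate:{gate}")
    if gate == EXCLUDED:
        return Classification("EXCLUDED", trace)
    if gate == PATH_ELIGIBLE:
        lof = rule_lof(record, cfg)
        trace.append(f"lof:{lof or 'no_call'}")
        if lof:
            return Classification(lof, trace)
        cv = rule_clinvar_concordance(record, cfg)
        trace.append(f"clinvar_concordance:{cv or 'no_call'}")
        if cv:
            return Classification(cv, trace)
    benign = _benign_call(record, cfg)
    trace.append(f"benign_concordance:{benign or 'no_call'}")
    if benign:
        return Classification(benign, trace)
    trace.append("default:VUS")
    return Classification("VUS", trace)


def resolve_consensus(call_primary: Classification,
                      call_secondary: Classification) -> Classification:
    """Merge the rule-engine call with the second-methodology call.

    Concordant calls are final. Discordant calls keep the primary label,
    raise the review flag, and record both calls in the trace — the
    pipeline queues them for expert review rather than adjudicating.
    P survives only when both methodologies assert P.
    """
    if call_primary.label == call_secondary.label:
        return Classification(call_primary.label,
                              call_primary.rule_trace + ["consensus:concordant"],
                              review_flag=call_primary.review_flag)
    trace = call_primary.rule_trace + [
        f"consensus:discordant(primary={call_primary.label},"
        f"secondary={call_secondary.label})"]
    return Classification(call_primary.label, trace, review_flag=True)


def classify_all(records: Iterable[VariantRecord],
                 cfg: ClassifierConfig | None = None,
                 secondary: Mapping[str, str] | None = None,
                 ) -> dict[tuple[str, str], Classification]:
    """Classify a corpus; key = (sample_id, variant_key).

    ``secondary`` optionally maps variant keys to the second
    methodology's labels; present keys are merged via
    :func:`resolve_consensus`.
    """
    cfg = cfg or ClassifierConfig()
    out: dict[tuple[str, str], Classification] = {}
    for r in records:
        c = classify(r, cfg)
        if secondary and r.variant_key in secondary:
            c = resolve_consensus(
                c, Classification(secondary[r.variant_key]))
        key = (r.sample_id, r.variant_key)
        if key in out:
            raise ValueError(f"duplicate sample-variant key {key}")
        out[key] = c
    return out


def write_classifications(calls: Mapping[tuple[str, str], Classification],
                          path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tvariant_key\tlabel\trule_trace\treview_flag\n")
        for (sid, vkey), c in calls.items():
            fh.write(f"{sid}\t{vkey}\t{c.label}\t{';'.join(c.rule_trace)}\t"
                     f"{int(c.review_flag)}\n")
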