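"""Rule-engine fixtures and invariants for variant classification."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from panelcc.classify import (ClassifierConfig, Classification, af_gate,
                              classify, classify_all, resolve_consensus,
                              rule_clinvar_concordance, rule_lof,
                              EXCLUDED, PATH_ELIGIBLE, VUS_CEILING)

from conftest import make_record

CFG = ClassifierConfig()


class TestAfGate:
    def test_common_variant_excluded(self):
        rec = make_record(pop_af={"ExAC": 0.05})
        assert af_gate(rec, CFG) == EXCLUDED

    def test_absent_afs_are_path_eligible(self):
        assert af_gate(make_record(), CFG) == PATH_ELIGIBLE

    def test_mid_band_caps_at_vus(self):
        rec = make_record(pop_af={"ESP6500": 0.01})
        assert af_gate(rec, CFG) == VUS_CEILING

    def test_chek2_1100delc_bypasses_both_gates(self):
        rec = make_record("CHEK2", "frameshift", hgvs_c="c.1100delC",
                          pop_af={"ExAC": 0.004})
        assert af_gate(rec, CFG) == PATH_ELIGIBLE
        assert classify(rec, CFG).label == "LP"


class TestLofRule:
    def test_nonsense_is_lp(self):
        rec = make_record(consequence="nonsense", pop_af={"ExAC": 0.001})
        assert rule_lof(rec, CFG) == "LP"
        assert classify(rec, CFG).label == "LP"

    def test_truncation_beyond_benign_boundary_falls_through(self):
        cfg = ClassifierConfig(benign_truncation_boundaries={"ATM": 5000})
        rec = make_record("ATM", "frameshift", pos=6000)
        assert rule_lof(rec, cfg) is None
        assert classify(rec, cfg).label == "VUS"

    def test_splice_plus_three_no_call(self):
        rec = make_record(consequence="splice_site", splice_offset=3)
        assert rule_lof(rec, CFG) is None

    @pytest.mark.parametrize("offset", [-2, -1, 1, 2])
    def test_canonical_splice_is_lp(self, offset):
        rec = make_record(consequence="splice_site", splice_offset=offset)
        assert rule_lof(rec, CFG) == "LP"


class TestClinvarConcordance:
    def test_two_trusted_submitters(self):
        rec = make_record("ATM", "missense",
                          clinvar=[("Ambry", "LP"), ("GeneDX", "P")])
        assert rule_clinvar_concordance(rec, CFG) == "LP"

    def test_one_submitter_insufficient(self):
        rec = make_record("ATM", "missense", clinvar=[("Ambry", "LP")])
        assert rule_clinvar_concordance(rec, CFG) is None
        assert classify(rec, CFG).label == "VUS"

    def test_tp53_single_submitter_override(self):
        rec = make_record("TP53", "missense", clinvar=[("GeneDX", "P")])
        assert rule_clinvar_concordance(rec, CFG) == "LP"

    def test_untrusted_submitters_ignored(self):
        rec = make_record("ATM", "missense",
                          clinvar=[("SomeLab", "P"), ("OtherLab", "P")])
        assert rule_clinvar_concordance(rec, CFG) is None

    def test_same_submitter_counts_once(self):
        rec = make_record("ATM", "missense",
                          clinvar=[("Ambry", "P"), ("Ambry", "LP")])
        assert rule_clinvar_concordance(rec, CFG) is None


class TestClassify:
    def test_low_risk_allele(self):
        rec = make_record("CHEK2", "missense", hgvs_p="p.I157T",
                          pop_af={"ExAC": 0.005})
        assert classify(rec, CFG).label == "LOW_RISK"

    def test_synonymous_without_assertions_is_vus(self):
        assert classify(make_record(consequence="synonymous"),
                        CFG).label == "VUS"

    def test_missing_consequence_flags_review(self):
        c = classify(make_record(consequence=None), CFG)
        assert c.label == "VUS" and c.review_flag

    def test_benign_concordance(self):
        rec = make_record("ATM", "missense",
                          clinvar=[("Ambry", "B"), ("GeneDX", "B")])
        assert classify(rec, CFG).label == "B"
        rec = make_record("ATM", "missense",
                          clinvar=[("Ambry", "B"), ("GeneDX", "LB")])
        assert classify(rec, CFG).label == "LB"

    def test_vus_ceiling_blocks_pathogenic_call(self):
        rec = make_record(consequence="nonsense", pop_af={"ExAC": 0.01})
        assert classify(rec, CFG).label == "VUS"

    def test_rule_trace_nonempty_for_non_vus(self):
        rec = make_record(consequence="nonsense")
        c = classify(rec, CFG)
        assert c.rule_trace and c.label == "LP"


class TestConsensus:
    def test_concordant_accepted(self):
        out = resolve_consensus(Classification("LP", ["lof:LP"]),
                                Classification("LP"))
        assert out.label == "LP" and not out.review_flag

    def test_discordant_keeps_primary_and_flags(self):
        out = resolve_consensus(Classification("LP", ["lof:LP"]),
                                Classification("VUS"))
        assert out.label == "LP" and out.review_flag
        assert any("discordant" in t for t in out.rule_trace)

    def test_concordant_vus(self):
        out = resolve_consensus(Classification("VUS"), Classification("VUS"))
        assert out.label == "VUS"


class TestCorpus:
    def test_planted_corpus_is_about_four_percent_pathogenic(self, cohort):
        """Mirrors the study spectrum: ~4% of unique variants are P/LP."""
        by_variant = {}
        for r in cohort.records:
            if (r.sample_id, r.variant_key) in cohort.truth.artifact_record_keys:
                continue
            by_variant.setdefault(r.variant_key, r)
        labels = [classify(r, cohort.classifier_config).label
                  for r in by_variant.values()]
        frac = sum(l in ("P", "LP") for l in labels) / len(labels)
        assert 0.03 <= frac <= 0.05

    def test_planted_labels_reproduced_by_engine(self, cohort):
        """Every planted P/LP classifies P/LP; no planted benign does."""
        seen = {}
        for r in cohort.records:
            if r.variant_key not in seen:
                seen[r.variant_key] = classify(
                    r, cohort.classifier_config).label
        for key, planted in cohort.truth.labels.items():
            got = seen[key]
            if planted in ("P", "LP"):
                assert got in ("P", "LP")
            else:
                assert got not in ("P", "LP")
                if planted == "LOW_RISK":
                    assert got == "LOW_RISK"

    def test_order_independence(self, cohort):
        records = cohort.records[:400]
        ref = {(r.sample_id, r.variant_key): c.label
               for (r, c) in zip(records,
                                 (classify(r, cohort.classifier_config)
                                  for r in records))}
        shuffled = records[:]
        random.Random(5).shuffle(shuffled)
        out = classify_all(shuffled, cohort.classifier_config)
        assert {k: c.label for k, c in out.items()} == ref


# --- property suites -------------------------------------------------------

_LABEL_RANK = {"B": 0, "LB": 1, "VUS": 2, "LP": 3, "P": 4}

conseq_st = st.sampled_from(["nonsense", "frameshift", "missense",
                             "synonymous", "intronic", "splice_site",
                             "other_noncoding"])
assertion_st = st.lists(
    st.tuples(st.sampled_from(["Ambry", "GeneDX", "InVitae", "SomeLab"]),
              st.sampled_from(["P", "LP", "VUS", "LB", "B"])),
    max_size=4)


@st.composite
def record_st(draw):
    conseq = draw(conseq_st)
    offset = draw(st.sampled_from([-3, -2, -1, 1, 2, 3, 5])) \
        if conseq == "splice_site" else None
    af = draw(st.one_of(st.none(),
                        st.floats(0, 0.1, allow_nan=False)))
    return make_record(
        draw(st.sampled_from(["ATM", "TP53", "CHEK2"])), conseq,
        splice_offset=offset, clinvar=draw(assertion_st),
        pop_af={} if af is None else {"ExAC": af})


@settings(max_examples=150, deadline=None, derandomize=True)
@given(record_st())
def test_removing_pathogenic_assertion_never_upgrades(rec):
    before = classify(rec, CFG).label
    stripped = [a for a in rec.clinvar if a[1] not in ("P", "LP")]
    rec2 = make_record(rec.gene, rec.consequence,
                       splice_offset=rec.splice_offset, clinvar=stripped,
                       pop_af=rec.pop_af)
    after = classify(rec2, CFG).label
    if before in _LABEL_RANK and after in _LABEL_RANK:
        assert _LABEL_RANK[after] <= _LABEL_RANK[before]


@settings(max_examples=150, deadline=None, derandomize=True)
@given(record_st(), st.floats(0.0001, 0.5, allow_nan=False))
def test_raising_af_never_upgrades(rec, bump):
    before = classify(rec, CFG).label
    af = rec.pop_af.get("ExAC", 0.0)
    rec2 = make_record(rec.gene, rec.consequence,
                       splice_offset=rec.splice_offset, clinvar=rec.clinvar,
                       pop_af={"ExAC": min(1.0, af + bump)})
    after = classify(rec2, CFG).label
    if before in _LABEL_RANK and after in _LABEL_RANK:
        assert _LABEL_RANK[after] <= _LABEL_RANK[before]


@settings(max_examples=150, deadline=None, derandomize=True)
@given(record_st())
def test_pathogenic_implies_rare_or_exception(rec):
    c = classify(rec, CFG)
    if c.label in ("P", "LP"):
        keys = {f"{rec.gene} {rec.hgvs_c}", f"{rec.gene} {rec.hgvs_p}"}
        assert (all(af <= 0.003 for af in rec.pop_af.values())
                or keys & CFG.exception_variants)


def test_low_risk_and_excluded_are_absorbing():
    low = make_record("CHEK2", "nonsense", hgvs_p="p.I157T",
                      clinvar=[("Ambry", "P"), ("GeneDX", "P")])
    assert classify(low, CFG).label == "LOW_RISK"
    common = make_record("ATM", "nonsense", pop_af={"ExAC": 0.2},
                         clinvar=[("Ambry", "P"), ("GeneDX", "P")])
    assert classify(common, CFG).label == "EXCLUDED"


def test_config_yaml_round_trip(tmp_path):
    cfg = ClassifierConfig(benign_truncation_boundaries={"ATM": 5000},
                           exon_lengths={"ATM": (10, 20, 30)})
    path = tmp_path / "classifier.yaml"
    cfg.to_yaml(path)
    assert ClassifierConfig.from_yaml(path) == cfg
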