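"""Carrier and allele-count bookkeeping (mutation-spectrum arithmetic)."""

import pytest

from panelcc.classify import Classification
from panelcc.cnv import CnvCall
from panelcc.tally import derive_case_AN, tally_carriers

from conftest import make_record

LP = lambda: Classification("LP", ["lof:LP"])


class TestDeriveCaseAN:
    def test_study_numbers(self):
        assert derive_case_AN(2134, 14) == 4254

    def test_zero_exclusions(self):
        assert derive_case_AN(1000) == 2000

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            derive_case_AN(0)


class TestPlantedComposition:
    """The planted cohort reproduces the study's allele-count arithmetic."""

    def test_case_allele_counts_after_exclusions(self, pipeline_run):
        tb = pipeline_run["tallies"]
        expected = {"ATM": 24, "CHEK2_trunc": 23, "PALB2": 17, "TP53": 11,
                    "BARD1": 7, "RAD51D": 4}
        for gene, ac in expected.items():
            assert tb[gene].case_ac == ac, gene
            assert tb[gene].case_an == 4254

    def test_carrier_counts_and_breakdown(self, pipeline_run):
        tb = pipeline_run["tallies"]
        atm = tb["ATM"]
        assert atm.n_carriers == 32
        assert atm.n_cnv_carriers == 5 and atm.n_double_carriers == 3
        chek2 = tb["CHEK2"]
        assert chek2.n_carriers == 35
        assert chek2.type_breakdown["indel_nonsense"] == 25
        assert chek2.type_breakdown["splicing"] == 2
        assert chek2.type_breakdown["missense"] == 3
        assert chek2.type_breakdown["cnv"] == 5

    def test_overall_summary(self, pipeline_run):
        s = pipeline_run["summary"]
        assert s.n_unique_carriers == 175
        assert s.n_double_carriers == 6
        assert round(100 * s.carrier_rate, 1) == 8.2
        pairs = sorted(p for _, p in s.double_carrier_pairs)
        assert pairs == [("ATM", "CHEK2"), ("ATM", "CHEK2"),
                         ("ATM", "RAD50"), ("CHEK2", "PALB2"),
                         ("CHEK2", "PALB2"), ("MSH6", "RAD50")]

    def test_group_rates(self, pipeline_run):
        tb = pipeline_run["tallies"]
        panel = pipeline_run["cohort"].panel
        sums = {grp: sum(tb[g].n_carriers for g in panel.genes_in_group(grp))
                for grp in ("high", "moderate", "proposed", "lynch", "mutyh")}
        assert sums["high"] == 30 and round(100 * 30 / 2134, 1) == 1.4
        assert sums["moderate"] == 68 and round(100 * 68 / 2134, 2) == 3.19
        assert sums["proposed"] == 39 and round(100 * 39 / 2134, 2) == 1.83
        assert sums["lynch"] == 11 and round(100 * 11 / 2134, 2) == 0.52
        assert sums["mutyh"] == 33 and round(100 * 33 / 2134, 2) == 1.55

    def test_gene_carrier_sum_identity(self, pipeline_run):
        """Sum over genes of carriers = unique carriers + double carriers."""
        tb = pipeline_run["tallies"]
        s = pipeline_run["summary"]
        total = sum(t.n_carriers for g, t in tb.items()
                    if not g.endswith("_trunc"))
        assert total == s.n_unique_carriers + s.n_double_carriers

    def test_case_ac_bounded_by_carriers(self, pipeline_run):
        for t in pipeline_run["tallies"].values():
            assert 0 <= t.case_ac <= t.n_carriers


class TestSmallCases:
    def test_double_carrier_counted_once_overall_twice_per_gene(self, panel):
        calls = [(make_record("ATM", "nonsense", sample_id="W1"), LP()),
                 (make_record("CHEK2", "nonsense", sample_id="W1", pos=7),
                  LP()),
                 (make_record("ATM", "nonsense", sample_id="W2", pos=9),
                  LP())]
        tallies, _, summary = tally_carriers(calls, [], panel, 100)
        tb = {t.gene: t for t in tallies}
        assert summary.n_unique_carriers == 2
        assert summary.n_double_carriers == 1
        assert tb["ATM"].n_carriers == 2 and tb["CHEK2"].n_carriers == 1
        # the double carrier is excluded from both genes' allele counts
        assert tb["ATM"].case_ac == 1 and tb["CHEK2"].case_ac == 0

    def test_cnv_carrier_excluded_from_ac_and_an(self, panel):
        calls = [(make_record("ATM", "nonsense", sample_id="W1"), LP())]
        cnvs = [(CnvCall("W2", "ATM", (2, 5), "deletion", "consensus"),
                 Classification("LP", ["cnv:frameshifting_deletion"]))]
        tallies, _, _ = tally_carriers(calls, cnvs, panel, 100)
        atm = {t.gene: t for t in tallies}["ATM"]
        assert atm.n_carriers == 2
        assert atm.case_ac == 1          # CNV carrier removed from AC
        assert atm.case_an == 199        # one allele removed per CNV case

    def test_duplicate_sample_variant_key_errors(self, panel):
        rec = make_record("ATM", "nonsense", sample_id="W1")
        with pytest.raises(ValueError, match="duplicate"):
            tally_carriers([(rec, LP()), (rec, LP())], [], panel, 10)

    def test_low_risk_tracked_separately(self, panel):
        calls = [(make_record("CHEK2", "missense", hgvs_p="p.I157T",
                              sample_id="W1"),
                  Classification("LOW_RISK", ["low_risk_allele"]))]
        tallies, _, summary = tally_carriers(calls, [], panel, 50)
        assert summary.n_unique_carriers == 0
        assert summary.n_low_risk_carriers == 1
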