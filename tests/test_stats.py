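"""Fisher exact test, odds ratios, confidence intervals, power."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from panelcc.stats import (PowerSpec, TwoByTwo, average_exac_allele_number,
                           control_individual_count, fisher_two_sided,
                           odds_ratio, or_confidence_interval,
                           power_by_simulation, run_case_control)


def fisher_oracle(table: TwoByTwo) -> Fraction:
    """Exact-rational minimum-likelihood two-sided Fisher p.

    Independent enumeration over the hypergeometric support using
    integer binomial coefficients only.
    """
    a, b, c, d = table.cells
    n, k, m = a + b + c + d, a + c, a + b
    if k == 0 or k == n or m == 0 or m == n:
        return Fraction(1)
    lo, hi = max(0, m + k - n), min(k, m)
    weights = {x: math.comb(k, x) * math.comb(n - k, m - x)
               for x in range(lo, hi + 1)}
    w_obs = weights[a]
    total = sum(weights.values())
    # ties handled exactly: include every table with weight <= observed
    p = Fraction(sum(w for w in weights.values() if w <= w_obs), total)
    return min(p, Fraction(1))


class TestFisher:
    def test_identical_arms_p_one(self):
        assert fisher_two_sided(TwoByTwo(1, 2, 1, 2)) == 1.0

    def test_zero_margin_p_one(self):
        assert fisher_two_sided(TwoByTwo(0, 10, 0, 20)) == 1.0

    def test_atm_table_matches_printed_p(self):
        p = fisher_two_sided(TwoByTwo(24, 4254, 92, 53288))
        assert p == pytest.approx(3.64e-6, rel=0.05)

    def test_matches_exact_enumeration_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            an1 = int(rng.integers(1, 31))
            an2 = int(rng.integers(1, 31))
            t = TwoByTwo(int(rng.integers(0, an1 + 1)), an1,
                         int(rng.integers(0, an2 + 1)), an2)
            assert fisher_two_sided(t) == pytest.approx(
                float(fisher_oracle(t)), rel=1e-9, abs=1e-12)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(18)
        for _ in range(100):
            an1, an2 = int(rng.integers(1, 200)), int(rng.integers(1, 2000))
            t = TwoByTwo(int(rng.integers(0, an1 + 1)), an1,
                         int(rng.integers(0, an2 + 1)), an2)
            a, b, c, d = t.cells
            expected = sps.fisher_exact([[a, b], [c, d]]).pvalue
            assert fisher_two_sided(t) == pytest.approx(expected, rel=1e-6)

    def test_arm_swap_invariance(self):
        t = TwoByTwo(24, 4254, 92, 53288)
        assert fisher_two_sided(t) == pytest.approx(
            fisher_two_sided(t.swapped()), rel=1e-12)


class TestOddsRatio:
    @pytest.mark.parametrize("table,expected", [
        ((24, 4254, 92, 53288), 3.28),
        ((17, 4254, 31, 53738), 6.95),
        ((11, 4254, 17, 53579), 8.17),
        ((7, 4254, 27, 52157), 3.18),
        ((23, 4254, 169, 50448), 1.62),
        ((4, 4254, 6, 53110), 8.33),
        ((33, 4254, 396, 53063), 1.04),
        ((7, 4254, 184, 53071), 0.47),
    ])
    def test_printed_or_reproduced(self, table, expected):
        assert round(odds_ratio(TwoByTwo(*table)), 2) == expected

    def test_equal_afs_give_unity(self):
        assert odds_ratio(TwoByTwo(5, 100, 50, 1000)) == pytest.approx(1.0)

    def test_swap_gives_reciprocal(self):
        t = TwoByTwo(24, 4254, 92, 53288)
        assert odds_ratio(t.swapped()) == pytest.approx(1 / odds_ratio(t))

    def test_zero_control_ac_open_upper(self):
        assert math.isinf(odds_ratio(TwoByTwo(3, 100, 0, 1000)))

    def test_both_zero_undefined(self):
        assert math.isnan(odds_ratio(TwoByTwo(0, 100, 0, 1000)))

    def test_conditional_mle_matches_golden_section_oracle(self):
        """Conditional MLE maximizes the noncentral hypergeometric
        likelihood; verified by golden-section search on that surface."""
        tables = [TwoByTwo(5, 20, 3, 25), TwoByTwo(8, 30, 2, 28),
                  TwoByTwo(4, 15, 9, 18)]
        gr = (math.sqrt(5) - 1) / 2
        for t in tables:
            a, b, c, d = t.cells
            n, k, m = a + b + c + d, a + c, a + b

            def nll(log_or):
                return -sps.nchypergeom_fisher.logpmf(
                    a, n, m, k, math.exp(log_or))

            lo, hi = -5.0, 5.0
            for _ in range(80):
                x1 = hi - gr * (hi - lo)
                x2 = lo + gr * (hi - lo)
                if nll(x1) < nll(x2):
                    hi = x2
                else:
                    lo = x1
            oracle = math.exp((lo + hi) / 2)
            assert odds_ratio(t, "conditional_mle") == pytest.approx(
                oracle, rel=1e-3)


class TestConfidenceIntervals:
    def test_exact_conditional_consistent_with_printed(self):
        t = TwoByTwo(24, 4254, 92, 53288)
        lo, hi = or_confidence_interval(t)
        assert lo <= 3.28 <= hi
        # overlaps the study's (method-unstated) interval 2.06-5.21
        assert lo < 5.21 and hi > 2.06

    def test_woolf_symmetric_for_equal_cells(self):
        lo, hi = or_confidence_interval(TwoByTwo(5, 10, 5, 10), "woolf")
        assert math.log(lo) == pytest.approx(-math.log(hi))

    def test_exact_bounds_agree_with_tail_root_oracle(self):
        """CI endpoints are the ORs whose conditional tail probability
        equals alpha/2 (root-finding on the noncentral tails)."""
        from scipy.optimize import brentq
        for t in [TwoByTwo(5, 20, 3, 25), TwoByTwo(7, 18, 4, 30)]:
            a, b, c, d = t.cells
            n, k, m = a + b + c + d, a + c, a + b
            lo, hi = or_confidence_interval(t, "exact_conditional")

            def upper_tail(orr):  # P(X >= a | or)
                return sps.nchypergeom_fisher.sf(a - 1, n, m, k, orr) - 0.025

            def lower_tail(orr):  # P(X <= a | or)
                return sps.nchypergeom_fisher.cdf(a, n, m, k, orr) - 0.025

            assert brentq(upper_tail, 1e-6, 1e3) == pytest.approx(
                lo, abs=1e-4, rel=1e-4)
            assert brentq(lower_tail, 1e-6, 1e3) == pytest.approx(
                hi, abs=1e-4, rel=1e-4)

    def test_zero_cell_one_sided(self):
        lo, hi = or_confidence_interval(TwoByTwo(3, 100, 0, 1000))
        assert lo > 0 and math.isinf(hi)


class TestAveraging:
    def test_constant(self):
        assert average_exac_allele_number([53288, 53288]) == 53288

    def test_mean(self):
        assert average_exac_allele_number([52000, 54000]) == 53000

    def test_control_individual_denominator(self):
        assert control_individual_count([52750, 52750]) == 26375

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            average_exac_allele_number([])


class TestRunCaseControl:
    def test_significance_pattern_on_study_tables(self, pipeline_run):
        res = {r.gene: r for r in pipeline_run["results"]}
        assert {g for g, r in res.items() if r.significant} \
            == {"ATM", "PALB2", "TP53"}
        for gene in ("BARD1", "CHEK2_trunc", "RAD51D"):
            assert res[gene].significant_nominal and not res[gene].significant

    def test_rad51d_example(self):
        t = TwoByTwo(4, 4254, 6, 53110)
        assert round(odds_ratio(t), 2) == 8.33
        assert fisher_two_sided(t) == pytest.approx(0.0044, rel=0.05)

    def test_all_zero_cases_no_significance(self, cohort):
        from panelcc.tally import GeneTally
        tallies = [GeneTally(gene=g, case_ac=0, case_an=4254)
                   for g in ("RAD51D", "MSH2", "TP53")]
        res = run_case_control(tallies, cohort.control_table)
        assert res and not any(r.significant for r in res)

    def test_missing_control_gene_warns(self, caplog, cohort):
        from panelcc.tally import GeneTally
        tallies = [GeneTally(gene="BAP1", case_ac=0, case_an=4254),
                   GeneTally(gene="STK11", case_ac=1, case_an=4254)]
        with caplog.at_level("WARNING"):
            res = run_case_control(tallies, cohort.control_table)
        by_gene = {r.gene: r for r in res}
        assert by_gene["STK11"].table.control_ac == 0
        assert by_gene["STK11"].flagged
        assert "STK11" in caplog.text


class TestPower:
    def test_type_one_error_validity(self):
        """At RR = 1 the rejection rate must not exceed alpha (Fisher's
        exact test is valid, and conservative at rare-count margins:
        the attained level here is ~0.02-0.03, below the nominal 0.05)."""
        res = power_by_simulation(PowerSpec(rr=1.0, n_reps=600, seed=3))
        se = max(res.mc_se, (0.05 * 0.95 / 600) ** 0.5)
        assert res.power <= 0.05 + 3 * se
        assert res.power > 0.0

    def test_monotone_in_relative_risk(self):
        powers = [power_by_simulation(PowerSpec(rr=rr, n_reps=300,
                                                seed=5)).power
                  for rr in (2, 4, 8)]
        assert powers == sorted(powers)

    def test_infeasible_spec_errors(self):
        with pytest.raises(ValueError):
            PowerSpec(p0=0.6, rr=2.0)
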