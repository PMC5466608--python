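"""Sample QC: heterozygosity, kinship, the exclusion cascade, site filters."""

import numpy as np
import pytest

from panelcc.sample_qc import (QCConfig, SampleQCMetrics,
                               apply_sample_filters, compute_heterozygosity,
                               estimate_kinship, filter_sites_and_genotypes,
                               kinship_matrix)
from panelcc.cohort_io import SampleMeta

from conftest import make_record


class TestHeterozygosity:
    def test_all_het_vector(self):
        het, _ = compute_heterozygosity(np.ones(10, dtype=int))
        assert het == 1.0

    def test_hwe_identity_at_half(self):
        # p = 0.5 everywhere and observed het exactly 0.5 -> zero excess
        g = np.array([1, 0, 1, 2] * 5)
        het, excess = compute_heterozygosity(g, np.full(20, 0.5))
        assert het == 0.5
        assert excess == pytest.approx(0.0)

    def test_all_missing_marked_unknown(self):
        het, excess = compute_heterozygosity(np.full(8, -1))
        assert het is None and excess is None

    def test_males_fall_three_sd_below(self, cohort):
        """Hemizygous-coded males sit > 3 SD below the cohort het mean."""
        g = cohort.genotypes
        ids = cohort.sample_ids
        hets = np.array([compute_heterozygosity(row)[0] for row in g])
        mean, sd = hets.mean(), hets.std()
        males = set(cohort.truth.qc_males)
        male_hets = [h for sid, h in zip(ids, hets) if sid in males]
        assert all(h < mean - 3 * sd for h in male_hets)


class TestKinship:
    def test_self_comparison_is_duplicate_range(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, 200)
        est = estimate_kinship(g, g)
        assert est.phi == pytest.approx(0.5)
        assert est.phi > 0.354

    def test_symmetry_exact(self):
        rng = np.random.default_rng(1)
        a = rng.binomial(2, 0.4, 300)
        b = rng.binomial(2, 0.4, 300)
        assert estimate_kinship(a, b).phi == estimate_kinship(b, a).phi

    def test_parent_child_allele_dropping_oracle(self):
        # allele-dropping at 200 sites, AF 0.3, fixed seed
        rng = np.random.default_rng(42)
        phis = []
        for _ in range(50):
            p1 = rng.binomial(1, 0.3, 200) + rng.binomial(1, 0.3, 200)
            passed = np.where(p1 == 1, rng.binomial(1, 0.5, 200), p1 // 2)
            child = passed + rng.binomial(1, 0.3, 200)
            phis.append(estimate_kinship(p1, child).phi)
        assert 0.2 <= np.mean(phis) <= 0.3

    def test_unrelated_pairs_near_zero(self):
        rng = np.random.default_rng(43)
        phis = []
        for _ in range(50):
            a = rng.binomial(2, 0.3, 200)
            b = rng.binomial(2, 0.3, 200)
            phis.append(estimate_kinship(a, b).phi)
        assert abs(np.mean(phis)) < 0.05

    def test_below_site_floor_unreliable(self):
        a = np.array([1, 1, 0, 2, 1])
        assert not estimate_kinship(a, a, min_sites=50).reliable

    def test_first_degree_sensitivity_at_200_sites(self):
        """Planted parent-child pairs exceed 0.177 >= 95% of the time."""
        rng = np.random.default_rng(7)
        hits = 0
        n_pairs = 200
        for _ in range(n_pairs):
            p = rng.uniform(0.2, 0.5, 200)
            parent = rng.binomial(2, p)
            passed = np.where(parent == 1, rng.binomial(1, 0.5, 200),
                              parent // 2)
            child = passed + rng.binomial(1, p)
            hits += estimate_kinship(parent, child).phi > 0.177
        assert hits / n_pairs >= 0.95

    def test_matrix_matches_pairwise(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.35, size=(6, 150))
        g[g > 2] = 2
        phi = kinship_matrix(g)
        for i in range(6):
            for j in range(i + 1, 6):
                assert phi[i, j] == pytest.approx(
                    estimate_kinship(g[i], g[j]).phi)


def _meta(sid, reads=5_000_000, cov=80.0, brca="negative"):
    return SampleMeta(sample_id=sid, n_reads=reads, mean_bait_coverage=cov,
                      brca_status=brca)


class TestExclusionCascade:
    def test_study_cascade_counts(self, pipeline_run):
        """2266 enrolled -> 2211 after quality/relatedness -> 2134 cases."""
        counts = pipeline_run["manifest"].counts
        assert counts["samples_in"] == 2266
        assert counts["samples_kept"] == 2134
        # BRCA-positive removals happen after the quality trim
        ledger = None  # reasons asserted via the cohort truth instead
        cohort = pipeline_run["cohort"]
        assert counts["samples_removed"] - len(cohort.truth.brca_positive) \
            == 2266 - 2211

    def test_ledger_is_partition(self, cohort):
        from panelcc.sample_qc import compute_cohort_metrics
        metrics = compute_cohort_metrics(
            cohort.genotypes, cohort.sample_ids, cohort.meta,
            allele_freqs=cohort.allele_freqs,
            x_marker_idx=cohort.x_marker_idx)
        kept, ledger = apply_sample_filters(metrics, cohort.meta)
        assert len(kept) + len(ledger) == len(cohort.sample_ids)
        assert ledger.sample_id.is_unique
        assert kept.isdisjoint(set(ledger.sample_id))

    def test_no_failures_keeps_all(self):
        metrics = [SampleQCMetrics(f"S{i}", heterozygosity=0.4)
                   for i in range(5)]
        meta = [_meta(f"S{i}") for i in range(5)]
        kept, ledger = apply_sample_filters(metrics, meta)
        assert len(kept) == 5 and len(ledger) == 0

    def test_duplicate_pair_removes_exactly_one(self):
        metrics = [SampleQCMetrics("A", 0.4, kinship={"B": 0.49}),
                   SampleQCMetrics("B", 0.4, kinship={"A": 0.49}),
                   SampleQCMetrics("C", 0.4)]
        meta = [_meta("A", cov=50), _meta("B", cov=90), _meta("C")]
        kept, ledger = apply_sample_filters(metrics, meta)
        assert kept == {"B", "C"}  # lower-coverage member removed
        assert ledger.reason.tolist() == ["duplicate"]

    def test_precedence_low_reads_first(self):
        m = [SampleQCMetrics("A", 0.4, kinship={"B": 0.2}),
             SampleQCMetrics("B", 0.4, kinship={"A": 0.2})]
        meta = [_meta("A", reads=100), _meta("B")]
        kept, ledger = apply_sample_filters(m, meta)
        # A removed for reads; pair rule then leaves B alone
        assert ledger.set_index("sample_id").reason["A"] == "low_reads"
        assert kept == {"B"}


class TestSiteFilters:
    def test_allelic_ratio_bounds_inclusive(self):
        records = [make_record(allelic_ratio=0.19),
                   make_record(allelic_ratio=0.20, pos=2),
                   make_record(allelic_ratio=0.80, pos=3),
                   make_record(allelic_ratio=0.81, pos=4)]
        kept, flog = filter_sites_and_genotypes(records)
        assert [r.allelic_ratio for r in kept] == [0.20, 0.80]
        assert flog.n_allelic_ratio == 2

    def test_low_call_rate_site_removed(self):
        records = [make_record(site_call_rate=0.49),
                   make_record(site_call_rate=0.50, pos=2)]
        kept, flog = filter_sites_and_genotypes(records)
        assert len(kept) == 1 and flog.n_call_rate == 1

    def test_missing_ratio_retained_and_flagged(self):
        records = [make_record(allelic_ratio=None)]
        kept, flog = filter_sites_and_genotypes(records)
        assert len(kept) == 1 and flog.n_flagged_missing_ratio == 1

    def test_planted_counting(self):
        rng = np.random.default_rng(3)
        records = [make_record(allelic_ratio=float(r), pos=i + 1)
                   for i, r in enumerate(rng.uniform(0.3, 0.7, 90))]
        records += [make_record(allelic_ratio=0.05, pos=100 + i)
                    for i in range(10)]
        kept, _ = filter_sites_and_genotypes(records)
        assert len(kept) == 90

    def test_idempotent(self):
        records = [make_record(allelic_ratio=0.5),
                   make_record(allelic_ratio=0.1, pos=2),
                   make_record(allelic_ratio=None, pos=3)]
        once, _ = filter_sites_and_genotypes(records)
        twice, _ = filter_sites_and_genotypes(once)
        assert once == twice


def test_qc_config_validation():
    with pytest.raises(ValueError):
        QCConfig(allelic_ratio_window=(0.8, 0.2))
    with pytest.raises(ValueError):
        QCConfig(min_reads=0)
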