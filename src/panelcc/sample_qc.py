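"""Sample- and site-level quality control.

Samples are excluded in a fixed precedence cascade — low read count,
low mean bait coverage, heterozygosity outlier (beyond +/-3 SD of the
cohort mean), inferred male, duplicate/first-degree kinship (one member
of each flagged pair), and prior BRCA1/2-positive status — producing an
exclusion ledger in which every removed sample has exactly one primary
reason. Variant calls are additionally required to have an alternate
allelic ratio inside a configurable window (default 20-80%, inclusive)
and a site-specific genotype call rate of at least 50%.

Genotypes are coded 0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing.

Sex inference is deliberately conservative: a sample is called male
only when its heterozygosity is more than ``het_sd_window`` SD below
the cohort mean *and* its X-linked markers (when the panel provides
any) are >= 99% homozygous; autosomal outliers without X support are
labeled heterozygosity outliers, never males.

Kinship uses the robust identity-by-state estimator of Manichaikul et
al. (KING-robust): phi = (N_het,het - 2 N_opp-hom) / (N_het(a) +
N_het(b)); duplicates sit near 0.5, first-degree pairs near 0.25,
unrelated pairs near 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import SampleMeta, VariantRecord

log = logging.getLogger(__name__)

EXCLUSION_PRECEDENCE = (
    "low_reads", "low_coverage", "heterozygosity_outlier", "male",
    "duplicate", "first_degree", "brca_positive",
)


@dataclass
class QCConfig:
    """Thresholds for the exclusion cascade and site filters."""

    min_reads: int = 1_000_000
    min_mean_coverage: float = 20.0
    het_sd_window: float = 3.0
    kinship_threshold: float = 0.177      # first-degree boundary
    duplicate_threshold: float = 0.354    # duplicate/monozygotic boundary
    min_site_call_rate: float = 0.5
    allelic_ratio_window: tuple[float, float] = (0.20, 0.80)
    min_kinship_sites: int = 50
    x_hom_fraction_male: float = 0.99

    def __post_init__(self) -> None:
        lo, hi = self.allelic_ratio_window
        if not (0 <= lo < hi <= 1):
            raise ValueError("allelic_ratio_window must be within [0,1], low < high")
        for name in ("min_reads", "min_mean_coverage", "het_sd_window",
                     "kinship_threshold", "min_site_call_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SampleQCMetrics:
    """Per-sample QC summary used by the exclusion cascade."""

    sample_id: str
    heterozygosity: float | None = None
    homozygosity_excess: float | None = None
    kinship: dict[str, float] = field(default_factory=dict)
    n_reads: int = 0
    mean_bait_coverage: float = 0.0
    inferred_sex: str = "unknown"  # male | female | unknown


@dataclass
class KinshipEstimate:
    phi: float
    n_sites: int
    reliable: bool


def compute_heterozygosity(genotypes: np.ndarray,
                           allele_freqs: np.ndarray | None = None,
                           ) -> tuple[float | None, float | None]:
    """Observed heterozygosity and excess homozygosity for one sample.

    Returns ``(het, hom_excess)`` where ``het`` is het calls over
    non-missing calls and ``hom_excess`` is observed minus
    Hardy-Weinberg-expected homozygosity (per-site expectation
    ``1 - 2 p (1 - p)``, averaged over the sample's non-missing sites).
    All-missing vectors return ``(None, None)``.
    """
    g = np.asarray(genotypes)
    called = g >= 0
    n = int(called.sum())
    if n == 0:
        return None, None
    het = float((g[called] == 1).mean())
    if allele_freqs is None:
        return het, None
    p = np.asarray(allele_freqs, dtype=float)[called]
    expected_hom = float(np.mean(1.0 - 2.0 * p * (1.0 - p)))
    return het, (1.0 - het) - expected_hom


def estimate_kinship(genotypes_a: np.ndarray, genotypes_b: np.ndarray,
                     min_sites: int = 50) -> KinshipEstimate:
    """KING-robust kinship between two genotype vectors.

    Pairs with fewer than ``min_sites`` shared non-missing sites are
    flagged unreliable (and must not be auto-excluded downstream).
    """
    a = np.asarray(genotypes_a)
    b = np.asarray(genotypes_b)
    if a.shape != b.shape:
        raise ValueError("genotype vectors differ in length")
    ok = (a >= 0) & (b >= 0)
    n = int(ok.sum())
    a, b = a[ok], b[ok]
    n_het_het = int(np.sum((a == 1) & (b == 1)))
    n_opp = int(np.sum(((a == 0) & (b == 2)) | ((a == 2) & (b == 0))))
    n_het_a = int(np.sum(a == 1))
    n_het_b = int(np.sum(b == 1))
    denom = n_het_a + n_het_b
    phi = float("nan") if denom == 0 else (n_het_het - 2.0 * n_opp) / denom
    return KinshipEstimate(phi=phi, n_sites=n, reliable=n >= min_sites)


def kinship_matrix(genotypes: np.ndarray) -> np.ndarray:
    """All-pairs KING-robust kinship for a samples x sites matrix.

    Vectorized over indicator matrices; missing calls (-1) at either
    member of a pair are ignored for the shared-site counts but the
    per-sample het counts follow the pairwise definition (hets over the
    pair's shared called sites), matching :func:`estimate_kinship`.
    """
    g = np.asarray(genotypes)
    het = (g == 1).astype(np.float64)
    aa = (g == 0).astype(np.float64)
    bb = (g == 2).astype(np.float64)
    called = (g >= 0).astype(np.float64)
    n_het_het = het @ het.T
    n_opp = aa @ bb.T + bb @ aa.T
    # hets of sample i over sites called in sample j (and vice versa)
    het_in_shared = het @ called.T
    denom = het_in_shared + het_in_shared.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_het_het - 2.0 * n_opp) / denom
    return phi


def compute_cohort_metrics(genotypes: np.ndarray, sample_ids: list[str],
                           meta: list[SampleMeta],
                           allele_freqs: np.ndarray | None = None,
                           x_marker_idx: np.ndarray | None = None,
                           cfg: QCConfig | None = None,
                           ) -> list[SampleQCMetrics]:
    """QC metrics for a whole cohort from its QC-SNP genotype matrix.

    ``kinship`` dicts store only partners at or above the first-degree
    threshold (the only pairs the cascade acts on). Sex inference
    follows the conservative rule described in the module docstring.
    The heterozygosity SD is computed over the full cohort, before any
    exclusions.
    """
    cfg = cfg or QCConfig()
    g = np.asarray(genotypes)
    if g.shape[0] != len(sample_ids) or len(meta) != len(sample_ids):
        raise ValueError("genotypes, sample_ids and meta must align")
    meta_by_id = {m.sample_id: m for m in meta}
    hets = np.full(len(sample_ids), np.nan)
    metrics: list[SampleQCMetrics] = []
    for i, sid in enumerate(sample_ids):
        het, excess = compute_heterozygosity(g[i], allele_freqs)
        hets[i] = np.nan if het is None else het
        m = meta_by_id[sid]
        metrics.append(SampleQCMetrics(
            sample_id=sid, heterozygosity=het, homozygosity_excess=excess,
            n_reads=m.n_reads, mean_bait_coverage=m.mean_bait_coverage))

    mean, sd = np.nanmean(hets), np.nanstd(hets)
    low_cut = mean - cfg.het_sd_window * sd
    for i, mtr in enumerate(metrics):
        if mtr.heterozygosity is None:
            continue
        if mtr.heterozygosity < low_cut and x_marker_idx is not None:
            xg = g[i, x_marker_idx]
            called = xg >= 0
            if called.any():
                x_hom = float((xg[called] != 1).mean())
                if x_hom >= cfg.x_hom_fraction_male:
                    mtr.inferred_sex = "male"

    phi = kinship_matrix(g)
    shared = ((g >= 0).astype(np.int64) @ (g >= 0).astype(np.int64).T)
    n = len(sample_ids)
    iu, ju = np.triu_indices(n, k=1)
    hit = np.nan_to_num(phi[iu, ju], nan=-1.0) > cfg.kinship_threshold
    for i, j in zip(iu[hit], ju[hit]):
        if shared[i, j] < cfg.min_kinship_sites:
            continue  # unreliable: never auto-excluded
        metrics[i].kinship[sample_ids[j]] = float(phi[i, j])
        metrics[j].kinship[sample_ids[i]] = float(phi[i, j])
    return metrics


def _het_bounds(metrics: list[SampleQCMetrics],
                cfg: QCConfig) -> tuple[float, float]:
    hets = np.array([m.heterozygosity for m in metrics
                     if m.heterozygosity is not None], dtype=float)
    if hets.size == 0:
        return -np.inf, np.inf
    mean, sd = float(hets.mean()), float(hets.std())
    return mean - cfg.het_sd_window * sd, mean + cfg.het_sd_window * sd


def apply_sample_filters(metrics: list[SampleQCMetrics],
                         meta: list[SampleMeta],
                         cfg: QCConfig | None = None,
                         ) -> tuple[set[str], pd.DataFrame]:
    """Run the exclusion cascade; return kept sample ids and the ledger.

    The ledger is a partition: every removed sample appears once, with
    its single primary reason (first matching stage in precedence
    order). For kinship-flagged pairs exactly one member is removed —
    the one with lower mean bait coverage, ties broken lexicographically
    by sample id.
    """
    cfg = cfg or QCConfig()
    meta_by_id = {m.sample_id: m for m in meta}
    order = [m.sample_id for m in metrics]
    removed: dict[str, tuple[str, float | None, float | None]] = {}
    lo_het, hi_het = _het_bounds(metrics, cfg)

    def drop(sid: str, reason: str, value, threshold) -> None:
        if sid not in removed:
            removed[sid] = (reason, value, threshold)

    for m in metrics:
        mm = meta_by_id.get(m.sample_id)
        n_reads = mm.n_reads if mm else m.n_reads
        cov = mm.mean_bait_coverage if mm else m.mean_bait_coverage
        if n_reads < cfg.min_reads:
            drop(m.sample_id, "low_reads", n_reads, cfg.min_reads)
        elif cov < cfg.min_mean_coverage:
            drop(m.sample_id, "low_coverage", cov, cfg.min_mean_coverage)
        elif (m.heterozygosity is not None
              and not lo_het <= m.heterozygosity <= hi_het):
            if m.inferred_sex == "male":
                drop(m.sample_id, "male", m.heterozygosity, lo_het)
            else:
                drop(m.sample_id, "heterozygosity_outlier",
                     m.heterozygosity, cfg.het_sd_window)

    # kinship pairs among still-kept samples, deterministic order
    pairs: list[tuple[str, str, float]] = []
    seen = set()
    for m in metrics:
        for partner, phi in m.kinship.items():
            key = tuple(sorted((m.sample_id, partner)))
            if key not in seen:
                seen.add(key)
                pairs.append((*key, phi))
    for a, b, phi in sorted(pairs):
        if a in removed or b in removed:
            continue
        reason = ("duplicate" if phi > cfg.duplicate_threshold
                  else "first_degree")
        ca = meta_by_id[a].mean_bait_coverage if a in meta_by_id else 0.0
        cb = meta_by_id[b].mean_bait_coverage if b in meta_by_id else 0.0
        victim = a if (ca, a) < (cb, b) else b
        drop(victim, reason, phi, cfg.kinship_threshold)

    for m in meta:
        if m.sample_id in removed:
            continue
        if m.brca_status == "positive":
            drop(m.sample_id, "brca_positive", None, None)

    kept = {sid for sid in order if sid not in removed}
    ledger = pd.DataFrame(
        [(sid, *removed[sid]) for sid in order if sid in removed],
        columns=["sample_id", "reason", "metric_value", "threshold"])
    by_reason = ledger.reason.value_counts().to_dict() if len(ledger) else {}
    log.info("sample QC: kept %d of %d (%s)", len(kept), len(order),
             ", ".join(f"{r}={by_reason.get(r, 0)}"
                       for r in EXCLUSION_PRECEDENCE if by_reason.get(r)))
    return kept, ledger


@dataclass
class SiteFilterLog:
    n_input: int = 0
    n_kept: int = 0
    n_allelic_ratio: int = 0
    n_call_rate: int = 0
    n_flagged_missing_ratio: int = 0


def filter_sites_and_genotypes(records: list[VariantRecord],
                               cfg: QCConfig | None = None,
                               ) -> tuple[list[VariantRecord], SiteFilterLog]:
    """Drop calls outside the allelic-ratio window or at low-call-rate sites.

    Window bounds are inclusive. Records with a missing allelic ratio
    are retained and counted as flagged, never silently dropped.
    """
    cfg = cfg or QCConfig()
    lo, hi = cfg.allelic_ratio_window
    logrec = SiteFilterLog(n_input=len(records))
    kept: list[VariantRecord] = []
    for r in records:
        if (r.site_call_rate is not None
                and r.site_call_rate < cfg.min_site_call_rate):
            logrec.n_call_rate += 1
            continue
        if r.allelic_ratio is None:
            logrec.n_flagged_missing_ratio += 1
            kept.append(r)
            continue
        if not lo <= r.allelic_ratio <= hi:
            logrec.n_allelic_ratio += 1
            continue
        kept.append(r)
    logrec.n_kept = len(kept)
    log.info("site filters: kept %d/%d (allelic ratio %d, call rate %d, "
             "flagged missing ratio %d)", logrec.n_kept, logrec.n_input,
             logrec.n_allelic_ratio, logrec.n_call_rate,
             logrec.n_flagged_missing_ratio)
    return kept, logrec
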