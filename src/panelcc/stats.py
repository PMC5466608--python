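"""Allele-based 2x2 case-control inference and power simulation.

The association test is the two-sided Fisher exact test in its
minimum-likelihood form: with both margins fixed, the p-value is the
sum of central hypergeometric probabilities of every table whose
probability does not exceed the observed table's (a relative tolerance
of 1e-7 absorbs floating-point ties). The reported odds ratio is the
unconditional cross-product ad/bc; the conditional maximum-likelihood
estimate (maximizer of the noncentral hypergeometric likelihood) and
its exact conditional (Cornfield) confidence interval are available as
alternatives, alongside the Woolf log-OR interval.

Power for a planned case-control comparison is estimated by Monte
Carlo: carrier counts are drawn binomially in each arm and the same
Fisher test is applied to the person-level table per replicate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .cohort_io import ControlAlleleTable
from .tally import GeneTally, TRUNCATING_TYPES, _CONSEQ_TO_TYPE

log = logging.getLogger(__name__)

TIE_RELATIVE_TOLERANCE = 1e-7


@dataclass(frozen=True)
class TwoByTwo:
    """Alternate-allele counts (AC) and allele numbers (AN) per arm."""

    case_ac: int
    case_an: int
    control_ac: int
    control_an: int

    def __post_init__(self) -> None:
        for ac, an, arm in ((self.case_ac, self.case_an, "case"),
                            (self.control_ac, self.control_an, "control")):
            if not 0 <= ac <= an:
                raise ValueError(f"{arm} arm violates 0 <= AC <= AN "
                                 f"({ac}/{an})")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """(a, b, c, d) = (case alt, case ref, control alt, control ref)."""
        return (self.case_ac, self.case_an - self.case_ac,
                self.control_ac, self.control_an - self.control_ac)

    def swapped(self) -> "TwoByTwo":
        return TwoByTwo(self.control_ac, self.control_an,
                        self.case_ac, self.case_an)


@dataclass
class CaseControlResult:
    gene: str
    table: TwoByTwo
    case_af: float
    control_af: float
    or_point: float
    ci: tuple[float, float]
    p: float
    significant: bool
    significant_nominal: bool
    flagged: bool = False  # undefined OR (both AC zero) or missing control


def fisher_two_sided(table: TwoByTwo) -> float:
    """Minimum-likelihood two-sided Fisher exact p-value.

    Sums hypergeometric probabilities over the whole support for all
    tables no more probable than the observed one. Degenerate margins
    (no successes, no failures, or an empty arm) give p = 1.
    """
    a, b, c, d = table.cells
    n_total = a + b + c + d
    k_success = a + c
    n_draw = a + b
    if k_success == 0 or k_success == n_total or n_draw == 0 or n_draw == n_total:
        return 1.0
    lo = max(0, n_draw + k_success - n_total)
    hi = min(k_success, n_draw)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n_total, k_success, n_draw)
    p_obs = pmf[a - lo]
    mask = pmf <= p_obs * (1.0 + TIE_RELATIVE_TOLERANCE)
    if mask.all():
        return 1.0  # whole support included; avoid float-sum shortfall
    return min(1.0, float(pmf[mask].sum()))


def odds_ratio(table: TwoByTwo,
               method: Literal["unconditional", "conditional_mle"]
               = "unconditional") -> float:
    """Odds-ratio point estimate.

    ``unconditional`` is the cross-product ad/bc (the study's reported
    estimator); ``conditional_mle`` maximizes the noncentral
    hypergeometric likelihood. A zero control AC gives ``inf`` (open
    upper bound); both ACs zero gives ``nan`` (undefined, flag upstream).
    """
    a, b, c, d = table.cells
    if a == 0 and c == 0:
        return float("nan")
    if method == "unconditional":
        if c == 0 or b == 0:
            return float("inf")
        return (a * d) / (b * c)
    if method == "conditional_mle":
        return float(_scipy_odds_ratio([[a, b], [c, d]],
                                       kind="conditional").statistic)
    raise ValueError(f"unknown OR method {method!r}")


def or_confidence_interval(table: TwoByTwo,
                           method: Literal["exact_conditional", "woolf"]
                           = "exact_conditional",
                           level: float = 0.95) -> tuple[float, float]:
    """95% (by default) confidence interval for the odds ratio.

    ``exact_conditional`` inverts the noncentral hypergeometric tail
    probabilities at (1-level)/2 per side; ``woolf`` is
    log-OR +/- z * sqrt(sum of reciprocal cells), with a Haldane 0.5
    continuity correction when any cell is zero (keeping the finite
    side computable).
    """
    a, b, c, d = table.cells
    if method == "exact_conditional":
        res = _scipy_odds_ratio([[a, b], [c, d]], kind="conditional")
        lo, hi = res.confidence_interval(confidence_level=level)
        return float(lo), float(hi)
    if method == "woolf":
        cells = [a, b, c, d]
        if 0 in cells:
            cells = [x + 0.5 for x in cells]
        a_, b_, c_, d_ = cells
        log_or = math.log((a_ * d_) / (b_ * c_))
        se = math.sqrt(sum(1.0 / x for x in cells))
        z = sps.norm.ppf(0.5 + level / 2)
        return math.exp(log_or - z * se), math.exp(log_or + z * se)
    raise ValueError(f"unknown CI method {method!r}")


def average_exac_allele_number(per_site_an: Sequence[float]) -> int:
    """Arithmetic mean of per-site allele numbers, nearest integer."""
    if len(per_site_an) == 0:
        raise ValueError("no allele numbers to average")
    return int(round(float(np.mean(per_site_an))))


def control_individual_count(per_site_an: Sequence[float]) -> float:
    """Carrier-scale control denominator: averaged AN divided by two."""
    return average_exac_allele_number(per_site_an) / 2.0


# ---------------------------------------------------------------------------
# per-gene case-control driver

def _control_mutation_rows(controls: ControlAlleleTable, gene: str,
                           truncating_only: bool):
    df = controls.rows
    sub = df[df.gene == gene]
    if "classification" in sub.columns and sub.classification.notna().any():
        sub = sub[sub.classification.isin(["P", "LP"])]
    if truncating_only:
        types = sub.consequence.map(_CONSEQ_TO_TYPE)
        sub = sub[types.isin(TRUNCATING_TYPES)]
    return sub


def run_case_control(tallies: Iterable[GeneTally],
                     controls: ControlAlleleTable,
                     threshold: float = 0.002,
                     alpha: float = 0.05,
                     or_method: str = "unconditional",
                     ci_method: str = "exact_conditional",
                     ) -> list[CaseControlResult]:
    """One Fisher/OR result per gene with any case or control mutation.

    ``<GENE>_trunc`` tallies are matched to control rows of gene GENE
    restricted to truncating consequences. The control AN for a gene is
    the averaged per-variant AN of its counted mutation rows. Genes
    absent from the control table get control AC 0 (with the table-wide
    averaged AN) and a warning.
    """
    fallback_an = average_exac_allele_number(controls.rows.an.tolist()) \
        if len(controls) else 0
    results: list[CaseControlResult] = []
    for t in tallies:
        gene, trunc = t.gene, False
        if gene.endswith("_trunc"):
            gene, trunc = gene[:-len("_trunc")], True
        sub = _control_mutation_rows(controls, gene, trunc)
        flagged = False
        if len(sub):
            control_ac = int(sub.ac.sum())
            control_an = average_exac_allele_number(sub.an.tolist())
        else:
            log.warning("gene %s absent from control table; control AC = 0",
                        t.gene)
            control_ac, control_an, flagged = 0, fallback_an, True
        if t.case_ac == 0 and control_ac == 0:
            continue
        if control_an == 0:
            continue
        table = TwoByTwo(t.case_ac, t.case_an, control_ac, control_an)
        p = fisher_two_sided(table)
        orr = odds_ratio(table, or_method)
        ci = or_confidence_interval(table, ci_method)
        results.append(CaseControlResult(
            gene=t.gene, table=table,
            case_af=t.case_ac / t.case_an if t.case_an else 0.0,
            control_af=control_ac / control_an,
            or_point=orr, ci=ci, p=p,
            significant=p < threshold, significant_nominal=p < alpha,
            flagged=flagged or math.isnan(orr)))
    return results


# ---------------------------------------------------------------------------
# power

@dataclass
class PowerSpec:
    n_case: int = 2134
    n_control: int = 26_375
    p0: float = 0.001          # control carrier probability
    rr: float = 4.0            # relative risk; case rate = rr * p0
    alpha: float = 0.05
    n_reps: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p0 * self.rr > 1:
            raise ValueError("case carrier probability rr*p0 exceeds 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class PowerResult:
    power: float
    mc_se: float               # Monte-Carlo standard error
    ci95: tuple[float, float]  # power +/- 1.96 * se
    n_reps: int


def power_by_simulation(spec: PowerSpec) -> PowerResult:
    """Monte-Carlo power of the two-sided Fisher test on carrier counts.

    Each replicate draws case carriers ~ Binomial(n_case, rr*p0) and
    control carriers ~ Binomial(n_control, p0) and tests the
    person-level 2x2 at ``alpha``. Identical draws share one test
    evaluation (the test is deterministic in the table).
    """
    rng = np.random.default_rng(spec.seed)
    a = rng.binomial(spec.n_case, spec.rr * spec.p0, size=spec.n_reps)
    c = rng.binomial(spec.n_control, spec.p0, size=spec.n_reps)
    cache: dict[tuple[int, int], float] = {}
    hits = 0
    for ai, ci in zip(a.tolist(), c.tolist()):
        key = (ai, ci)
        p = cache.get(key)
        if p is None:
            p = fisher_two_sided(
                TwoByTwo(ai, spec.n_case, ci, spec.n_control))
            cache[key] = p
        hits += p < spec.alpha
    power = hits / spec.n_reps
    se = math.sqrt(power * (1 - power) / spec.n_reps)
    return PowerResult(power=power, mc_se=se,
                       ci95=(power - 1.96 * se, power + 1.96 * se),
                       n_reps=spec.n_reps)
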