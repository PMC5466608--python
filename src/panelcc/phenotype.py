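"""Carrier-vs-noncarrier phenotype contrasts.

Categorical traits (bilateral disease, receptor status, family-history
flags...) are compared with the same two-sided Fisher exact test used
for the case-control analysis; proportions are reported to the whole
percent. Age-at-diagnosis contrasts use Welch's unequal-variance
two-sample t-test — individual ages are cohort data, so no exact
printed target exists and the robust default is preferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats as sps

from .stats import TwoByTwo, fisher_two_sided

log = logging.getLogger(__name__)


@dataclass
class PhenotypeContrast:
    group_label: str
    trait: str
    carrier_k: int | None = None
    carrier_n: int | None = None
    noncarrier_k: int | None = None
    noncarrier_n: int | None = None
    carrier_pct: int | None = None     # whole percent
    noncarrier_pct: int | None = None
    carrier_mean: float | None = None  # continuous traits
    noncarrier_mean: float | None = None
    p: float | None = None
    skipped: bool = False


def compare_categorical(carrier_k: int, carrier_n: int,
                        noncarrier_k: int, noncarrier_n: int,
                        group_label: str = "", trait: str = "",
                        ) -> PhenotypeContrast:
    """Fisher two-sided comparison of a trait rate between arms.

    An empty arm (n = 0) yields a skipped contrast with a warning.
    """
    if carrier_n == 0 or noncarrier_n == 0:
        log.warning("phenotype contrast %s/%s skipped: empty arm",
                    group_label, trait)
        return PhenotypeContrast(group_label, trait, carrier_k, carrier_n,
                                 noncarrier_k, noncarrier_n, skipped=True)
    p = fisher_two_sided(TwoByTwo(carrier_k, carrier_n,
                                  noncarrier_k, noncarrier_n))
    return PhenotypeContrast(
        group_label, trait, carrier_k, carrier_n, noncarrier_k, noncarrier_n,
        carrier_pct=round(100 * carrier_k / carrier_n),
        noncarrier_pct=round(100 * noncarrier_k / noncarrier_n),
        p=p)


def compare_ages(ages_carrier: Sequence[float],
                 ages_noncarrier: Sequence[float],
                 group_label: str = "", trait: str = "age_at_diagnosis",
                 ) -> PhenotypeContrast:
    """Welch two-sided t-test on age samples; < 2 values per arm skips."""
    a, b = list(ages_carrier), list(ages_noncarrier)
    if len(a) < 2 or len(b) < 2:
        log.warning("age contrast %s skipped: fewer than 2 values per arm",
                    group_label)
        return PhenotypeContrast(group_label, trait, skipped=True)
    res = sps.ttest_ind(a, b, equal_var=False)
    return PhenotypeContrast(
        group_label, trait,
        carrier_mean=float(sum(a) / len(a)),
        noncarrier_mean=float(sum(b) / len(b)),
        p=float(res.pvalue))


def write_contrasts(contrasts: Iterable[PhenotypeContrast],
                    path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("group\ttrait\tcarrier_k\tcarrier_n\tcarrier_pct\t"
                 "noncarrier_k\tnoncarrier_n\tnoncarrier_pct\t"
                 "carrier_mean\tnoncarrier_mean\tp\tskipped\n")
        for c in contrasts:
            def d(v):
                return "." if v is None else (
                    f"{v:.6g}" if isinstance(v, float) else str(v))
            fh.write("\t".join([
                c.group_label, c.trait, d(c.carrier_k), d(c.carrier_n),
                d(c.carrier_pct), d(c.noncarrier_k), d(c.noncarrier_n),
                d(c.noncarrier_pct), d(c.carrier_mean), d(c.noncarrier_mean),
                d(c.p), str(int(c.skipped)),
            ]) + "\n")
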