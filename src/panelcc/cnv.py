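"""Copy-number variant consensus and classification.

Exon-resolution deletion/duplication calls from two independent
read-depth callers are intersected: a consensus event requires the same
sample, gene and type with at least one shared exon, and its span is
the intersection of the two call spans. Consensus deletions that
disrupt reading frame (sum of deleted exon lengths not divisible by 3,
from a per-gene exon-length table) or remove several exons are likely
pathogenic; whole-gene duplications and single-exon in-frame deletions
are VUS.

Control-population CNV summaries (ExAC-browser style) are filtered to
events comparable with the case calls: single-gene span, at least two
exons, and outside repetitive or pseudogene regions.

Coordinates are 1-based inclusive exon indices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

from .classify import Classification, ClassifierConfig

CNV_TYPES = ("deletion", "duplication")


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    gene: str
    exon_span: tuple[int, int]  # 1-based inclusive exon indices
    cnv_type: str
    caller: str
    n_genes_spanned: int = 1
    in_repetitive_or_pseudogene_region: bool = False
    whole_gene: bool = False
    confirmed: bool = True  # stands in for visual read-depth review

    def __post_init__(self) -> None:
        lo, hi = self.exon_span
        if lo > hi or lo < 1:
            raise ValueError(f"bad exon span {self.exon_span}")
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(f"bad cnv_type {self.cnv_type!r}")
        if self.n_genes_spanned < 1:
            raise ValueError("n_genes_spanned must be >= 1")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.sample_id, self.gene, self.cnv_type)

    @property
    def n_exons(self) -> int:
        return self.exon_span[1] - self.exon_span[0] + 1


def consensus_cnvs(calls_a: Iterable[CnvCall],
                   calls_b: Iterable[CnvCall]) -> list[CnvCall]:
    """Calls present in both sets; consensus span = span intersection.

    Commutative, and the output is a subset of each input by
    (sample, gene, type) key. When one caller reports several events for
    the same key, each overlapping pair yields one consensus event.
    """
    by_key: dict[tuple[str, str, str], list[CnvCall]] = {}
    for c in calls_b:
        by_key.setdefault(c.key, []).append(c)
    out: list[CnvCall] = []
    seen: set[tuple] = set()
    for a in calls_a:
        for b in by_key.get(a.key, []):
            lo = max(a.exon_span[0], b.exon_span[0])
            hi = min(a.exon_span[1], b.exon_span[1])
            if lo > hi:
                continue
            dedup = (*a.key, lo, hi)
            if dedup in seen:
                continue
            seen.add(dedup)
            out.append(replace(
                a, exon_span=(lo, hi), caller="consensus",
                whole_gene=a.whole_gene and b.whole_gene,
                confirmed=a.confirmed and b.confirmed))
    return sorted(out, key=lambda c: (c.sample_id, c.gene, c.cnv_type,
                                      c.exon_span))


def is_frameshifting(call: CnvCall, cfg: ClassifierConfig) -> bool | None:
    """Whether a deletion disrupts reading frame; None if unknown.

    Uses the configured per-gene exon-length table: frame is disrupted
    when the summed length of deleted exons is not a multiple of 3.
    """
    lengths = cfg.exon_lengths.get(call.gene)
    if lengths is None:
        return None
    lo, hi = call.exon_span
    if hi > len(lengths):
        return None
    return sum(lengths[lo - 1:hi]) % 3 != 0


def classify_cnv(call: CnvCall,
                 cfg: ClassifierConfig | None = None) -> Classification:
    """Classify a consensus CNV.

    Deletions are LP when truncating (frame-disrupting, or multi-exon
    without frame information); whole-gene deletions are LP outright.
    Whole-gene duplications and single-exon in-frame deletions are VUS,
    as are duplications generally (their transcript effect is not
    resolvable from read depth alone).
    """
    cfg = cfg or ClassifierConfig()
    if call.cnv_type == "duplication":
        reason = ("whole_gene_duplication" if call.whole_gene
                  else "duplication_unresolved")
        return Classification("VUS", [f"cnv:{reason}"])
    if call.whole_gene:
        return Classification("LP", ["cnv:whole_gene_deletion"])
    fs = is_frameshifting(call, cfg)
    if fs is False and call.n_exons == 1:
        return Classification("VUS", ["cnv:single_exon_in_frame_deletion"])
    if fs is False:
        return Classification("VUS", ["cnv:in_frame_deletion"])
    rule = "frameshifting_deletion" if fs else "multi_exon_deletion"
    if fs is None and call.n_exons == 1:
        return Classification("VUS", ["cnv:single_exon_unknown_frame"])
    return Classification("LP", [f"cnv:{rule}"])


def filter_control_cnvs(calls: Iterable[CnvCall]) -> list[CnvCall]:
    """Keep control CNVs comparable to case calls (idempotent).

    Single-gene span, not repetitive/pseudogene-flagged, covering at
    least two exons.
    """
    return [c for c in calls
            if c.n_genes_spanned == 1
            and not c.in_repetitive_or_pseudogene_region
            and c.n_exons >= 2]


# ---------------------------------------------------------------------------
# TSV interchange

_CNV_COLUMNS = ["sample_id", "gene", "exon_start", "exon_end", "type",
                "caller", "n_genes", "repeat_flag", "whole_gene", "confirmed"]


def write_cnv_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_CNV_COLUMNS) + "\n")
        for c in calls:
            fh.write("\t".join([
                c.sample_id, c.gene, str(c.exon_span[0]),
                str(c.exon_span[1]), c.cnv_type, c.caller,
                str(c.n_genes_spanned),
                str(int(c.in_repetitive_or_pseudogene_region)),
                str(int(c.whole_gene)), str(int(c.confirmed)),
            ]) + "\n")


def read_cnv_calls(path: str | Path) -> list[CnvCall]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != _CNV_COLUMNS:
        raise ValueError(f"{path}: unexpected CNV header {list(df.columns)}")
    return [CnvCall(
        sample_id=row.sample_id, gene=row.gene,
        exon_span=(int(row.exon_start), int(row.exon_end)),
        cnv_type=row.type, caller=row.caller,
        n_genes_spanned=int(row.n_genes),
        in_repetitive_or_pseudogene_region=row.repeat_flag == "1",
        whole_gene=row.whole_gene == "1", confirmed=row.confirmed == "1",
    ) for row in df.itertuples()]
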