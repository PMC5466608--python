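"""Domain records and readers/writers for all pipeline inputs and outputs.

One :class:`VariantRecord` is one annotated variant call in one sample.
Case variants arrive either as a VCF 4.2 with annotation INFO keys
(``SAMPLE, GENE, CONSEQ, SPLICE_OFFSET, AAF, EXAC_AF, ESP_AF, KG_AF,
CLNSUB, SITE_CALL_RATE``; one VCF line per sample-variant pair) or as a
tab-separated table in the dialect documented below. Control data are an
ExAC-style per-variant allele-count summary (AC/AN), never per-sample
genotypes. All TSVs are UTF-8, header row required, ``.`` for missing.

TSV dialect for case variants (columns, in order)::

    sample_id  gene  chrom  pos  ref  alt  hgvs_c  hgvs_p  consequence
    splice_offset  allelic_ratio  exac_af  esp_af  kg_af  clinvar
    site_pass  site_call_rate

``clinvar`` packs (submitter, assertion) pairs as
``Ambry:P|GeneDX:LP``; submitter names are percent-encoded so embedded
spaces survive both the TSV and VCF round trips.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence
from urllib.parse import quote, unquote

import pandas as pd
import pysam

from .panel import PanelConfig

if TYPE_CHECKING:  # pragma: no cover
    from .stats import CaseControlResult

log = logging.getLogger(__name__)

CONSEQUENCES = (
    "nonsense", "frameshift", "splice_site", "missense", "synonymous",
    "intronic", "other_noncoding", "whole_gene_deletion",
)
AF_SOURCES = ("ExAC", "ESP6500", "1000G")
_AF_COLUMNS = {"ExAC": "exac_af", "ESP6500": "esp_af", "1000G": "kg_af"}
CLINVAR_ASSERTIONS = ("P", "LP", "VUS", "LB", "B")

_CASE_COLUMNS = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt", "hgvs_c", "hgvs_p",
    "consequence", "splice_offset", "allelic_ratio", "exac_af", "esp_af",
    "kg_af", "clinvar", "site_pass", "site_call_rate",
]


@dataclass
class VariantRecord:
    """One annotated heterozygous variant call in one sample."""

    sample_id: str
    gene: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    consequence: str | None
    splice_offset: int | None = None  # signed, for splice_site only
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    allelic_ratio: float | None = None  # fraction of alternate reads
    pop_af: dict[str, float] = field(default_factory=dict)
    clinvar: list[tuple[str, str]] = field(default_factory=list)
    call_quality: bool = True  # per-site pass/fail
    site_call_rate: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.consequence is not None and self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.allelic_ratio is not None and not 0 <= self.allelic_ratio <= 1:
            raise ValueError(f"allelic_ratio outside [0,1]: {self.allelic_ratio}")
        for src, af in self.pop_af.items():
            if not 0 <= af <= 1:
                raise ValueError(f"pop_af[{src}] outside [0,1]: {af}")

    @property
    def variant_key(self) -> str:
        """Sample-independent identity of the variant."""
        return f"{self.gene}:{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def hgvs_key(self) -> str | None:
        """``GENE c.`` / ``GENE p.`` style key used for named exceptions."""
        if self.hgvs_c:
            return f"{self.gene} {self.hgvs_c}"
        return None


@dataclass
class ControlAlleleTable:
    """ExAC-style per-variant allele-count summary for the control arm.

    ``rows`` is a DataFrame with columns
    ``gene, variant_key, consequence, splice_offset, ac, an,
    classification`` (classification optional, may be NA); invariant
    0 <= AC <= AN, AN > 0 on every row.
    """

    rows: pd.DataFrame

    REQUIRED = ("gene", "variant_key", "ac", "an")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValueError(f"control table missing columns: {missing}")
        for col in ("consequence", "splice_offset", "classification"):
            if col not in self.rows.columns:
                self.rows[col] = pd.NA
        bad = self.rows[(self.rows.ac < 0) | (self.rows.ac > self.rows.an)
                        | (self.rows.an <= 0)]
        if len(bad):
            i = bad.index[0]
            raise ValueError(
                f"control table row {i} violates 0 <= AC <= AN, AN > 0: "
                f"AC={bad.ac.iloc[0]}, AN={bad.an.iloc[0]}")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class Phenotype:
    """Optional clinical bundle attached to a sample."""

    age_first_bc: float | None = None
    age_second_bc: float | None = None
    bilateral: bool | None = None
    er_status: str | None = None   # "+", "-", or None
    her2_status: str | None = None
    n_fdr_breast: int | None = None
    n_fdr_sdr_ovarian: int | None = None


@dataclass
class SampleMeta:
    """Per-sample sequencing and clinical metadata."""

    sample_id: str
    n_reads: int
    mean_bait_coverage: float
    brca_status: str = "negative"  # negative | positive | unknown
    phenotype: Phenotype | None = None

    def __post_init__(self) -> None:
        if self.n_reads < 0 or self.mean_bait_coverage < 0:
            raise ValueError("n_reads and mean_bait_coverage must be >= 0")
        if self.brca_status not in ("negative", "positive", "unknown"):
            raise ValueError(f"bad brca_status {self.brca_status!r}")


# ---------------------------------------------------------------------------
# helpers

def _dot(v) -> str:
    if v is None:
        return "."
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        if math.isnan(v):
            return "."
        return repr(v)
    return str(v)


def _undot(s: str):
    return None if s in (".", "", "nan") else s


def pack_clinvar(assertions: Sequence[tuple[str, str]]) -> str:
    if not assertions:
        return "."
    return "|".join(f"{quote(sub, safe='')}:{a}" for sub, a in assertions)


def unpack_clinvar(s: str | None) -> list[tuple[str, str]]:
    if not s or s == ".":
        return []
    out = []
    for item in s.split("|"):
        sub, _, a = item.rpartition(":")
        if a not in CLINVAR_ASSERTIONS:
            raise ValueError(f"bad ClinVar assertion {a!r} in {item!r}")
        out.append((unquote(sub), a))
    return out


def _record_to_row(r: VariantRecord) -> list[str]:
    return [
        r.sample_id, r.gene, r.chrom, str(r.pos), r.ref, r.alt,
        _dot(r.hgvs_c), _dot(r.hgvs_p), _dot(r.consequence),
        _dot(r.splice_offset),
        _dot(r.allelic_ratio),
        _dot(r.pop_af.get("ExAC")), _dot(r.pop_af.get("ESP6500")),
        _dot(r.pop_af.get("1000G")),
        pack_clinvar(r.clinvar), "1" if r.call_quality else "0",
        _dot(r.site_call_rate),
    ]


def _row_to_record(vals: dict[str, str]) -> VariantRecord:
    pop_af = {}
    for src, col in _AF_COLUMNS.items():
        v = _undot(vals[col])
        if v is not None:
            pop_af[src] = float(v)
    so = _undot(vals["splice_offset"])
    ar = _undot(vals["allelic_ratio"])
    scr = _undot(vals["site_call_rate"])
    return VariantRecord(
        sample_id=vals["sample_id"], gene=vals["gene"], chrom=vals["chrom"],
        pos=int(vals["pos"]), ref=vals["ref"], alt=vals["alt"],
        hgvs_c=_undot(vals["hgvs_c"]), hgvs_p=_undot(vals["hgvs_p"]),
        consequence=_undot(vals["consequence"]),
        splice_offset=None if so is None else int(so),
        allelic_ratio=None if ar is None else float(ar),
        pop_af=pop_af, clinvar=unpack_clinvar(vals["clinvar"]),
        call_quality=vals["site_pass"] == "1",
        site_call_rate=None if scr is None else float(scr),
    )


# ---------------------------------------------------------------------------
# case variants

def read_case_variants(path: str | Path,
                       panel: PanelConfig) -> list[VariantRecord]:
    """Read case variants (VCF or TSV); drop and count non-panel genes.

    Malformed rows raise ``ValueError`` naming the line; unknown gene
    symbols are dropped with a logged warning count.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        records, dropped = _read_vcf(path, panel)
    else:
        records, dropped = _read_tsv(path, panel)
    if dropped:
        log.warning("read_case_variants: dropped %d record(s) outside the "
                    "%d-gene panel", dropped, len(panel.genes))
    return records


def _read_tsv(path: Path, panel: PanelConfig):
    records: list[VariantRecord] = []
    dropped = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            return records, dropped  # empty file -> empty list
        cols = header.split("\t")
        if cols != _CASE_COLUMNS:
            raise ValueError(f"{path}: unexpected header {cols!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            vals = line.split("\t")
            if len(vals) != len(cols):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(cols)} fields, "
                    f"got {len(vals)}")
            row = dict(zip(cols, vals))
            if row["gene"] not in panel:
                dropped += 1
                continue
            try:
                records.append(_row_to_record(row))
            except (ValueError, KeyError) as e:
                raise ValueError(f"{path}: line {lineno}: {e}") from e
    return records, dropped


def write_case_variants(records: Iterable[VariantRecord],
                        path: str | Path) -> None:
    """Write case variants in the TSV dialect (lossless round trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_CASE_COLUMNS) + "\n")
        for r in records:
            fh.write("\t".join(_record_to_row(r)) + "\n")


_VCF_INFO = [
    ("SAMPLE", "1", "String", "Sample carrying this call"),
    ("GENE", "1", "String", "Panel gene symbol"),
    ("CONSEQ", "1", "String", "Annotated consequence"),
    ("SPLICE_OFFSET", "1", "Integer", "Signed offset from exon boundary"),
    ("HGVSC", "1", "String", "Transcript-level HGVS name"),
    ("HGVSP", "1", "String", "Protein-level HGVS name"),
    ("AAF", "1", "Float", "Alternate allelic ratio in this sample"),
    ("EXAC_AF", "1", "Float", "ExAC population allele frequency"),
    ("ESP_AF", "1", "Float", "ESP6500 population allele frequency"),
    ("KG_AF", "1", "Float", "1000 Genomes population allele frequency"),
    ("CLNSUB", "1", "String", "ClinVar submitter:assertion pairs"),
    ("SITE_CALL_RATE", "1", "Float", "Site-specific genotype call rate"),
]


def write_case_vcf(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write one VCF 4.2 line per sample-variant pair."""
    header = pysam.VariantHeader()
    for key, num, typ, desc in _VCF_INFO:
        header.info.add(key, num, typ, desc)
    header.filters.add("FAIL", None, None, "Per-site quality fail")
    records = list(records)
    for chrom in sorted({r.chrom for r in records}):
        header.contigs.add(chrom)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in records:
            rec = vcf.new_record(
                contig=r.chrom, start=r.pos - 1, stop=r.pos - 1 + len(r.ref),
                alleles=(r.ref, r.alt))
            rec.info["SAMPLE"] = r.sample_id
            rec.info["GENE"] = r.gene
            if r.consequence is not None:
                rec.info["CONSEQ"] = r.consequence
            if r.splice_offset is not None:
                rec.info["SPLICE_OFFSET"] = r.splice_offset
            if r.hgvs_c:
                rec.info["HGVSC"] = quote(r.hgvs_c, safe="")
            if r.hgvs_p:
                rec.info["HGVSP"] = quote(r.hgvs_p, safe="")
            if r.allelic_ratio is not None:
                rec.info["AAF"] = r.allelic_ratio
            for src, key in (("ExAC", "EXAC_AF"), ("ESP6500", "ESP_AF"),
                             ("1000G", "KG_AF")):
                if src in r.pop_af:
                    rec.info[key] = r.pop_af[src]
            if r.clinvar:
                rec.info["CLNSUB"] = pack_clinvar(r.clinvar)
            if r.site_call_rate is not None:
                rec.info["SITE_CALL_RATE"] = r.site_call_rate
            rec.filter.add("PASS" if r.call_quality else "FAIL")
            vcf.write(rec)


def _read_vcf(path: Path, panel: PanelConfig):
    records: list[VariantRecord] = []
    dropped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            gene = info.get("GENE")
            if gene not in panel:
                dropped += 1
                continue
            pop_af = {}
            for src, key in (("ExAC", "EXAC_AF"), ("ESP6500", "ESP_AF"),
                             ("1000G", "KG_AF")):
                if key in info:
                    # VCF floats are single precision; round to survive
                    # the double->float->double trip at input precision
                    pop_af[src] = round(float(info[key]), 6)
            aaf = round(float(info["AAF"]), 6) if "AAF" in info else None
            scr = (round(float(info["SITE_CALL_RATE"]), 6)
                   if "SITE_CALL_RATE" in info else None)
            records.append(VariantRecord(
                sample_id=info["SAMPLE"], gene=gene, chrom=rec.chrom,
                pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                consequence=info.get("CONSEQ"),
                splice_offset=(int(info["SPLICE_OFFSET"])
                               if "SPLICE_OFFSET" in info else None),
                hgvs_c=unquote(info["HGVSC"]) if "HGVSC" in info else None,
                hgvs_p=unquote(info["HGVSP"]) if "HGVSP" in info else None,
                allelic_ratio=aaf,
                pop_af=pop_af, clinvar=unpack_clinvar(info.get("CLNSUB")),
                call_quality="PASS" in rec.filter or len(rec.filter) == 0,
                site_call_rate=scr,
            ))
    return records, dropped


# ---------------------------------------------------------------------------
# control table

def read_control_table(path: str | Path) -> ControlAlleleTable:
    """Read the ExAC-style control allele-count TSV (AC/AN per variant)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "variant_key": str},
                     na_values=["."], keep_default_na=True)
    if "ac" in df.columns:
        df["ac"] = df["ac"].astype(int)
        df["an"] = df["an"].astype(int)
    if "splice_offset" in df.columns:
        df["splice_offset"] = df["splice_offset"].astype("Int64")
    return ControlAlleleTable(df)


def write_control_table(table: ControlAlleleTable, path: str | Path) -> None:
    table.rows.to_csv(path, sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------------------
# sample metadata

_META_COLUMNS = [
    "sample_id", "n_reads", "mean_bait_coverage", "brca_status",
    "age_first_bc", "age_second_bc", "bilateral", "er_status", "her2_status",
    "n_fdr_breast", "n_fdr_sdr_ovarian",
]


def write_sample_meta(meta: Iterable[SampleMeta], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_META_COLUMNS) + "\n")
        for m in meta:
            p = m.phenotype or Phenotype()
            fh.write("\t".join([
                m.sample_id, str(m.n_reads), repr(m.mean_bait_coverage),
                m.brca_status, _dot(p.age_first_bc), _dot(p.age_second_bc),
                _dot(p.bilateral), _dot(p.er_status), _dot(p.her2_status),
                _dot(p.n_fdr_breast), _dot(p.n_fdr_sdr_ovarian),
            ]) + "\n")


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    out: list[SampleMeta] = []
    with open(path, encoding="utf-8") as fh:
        cols = fh.readline().rstrip("\n").split("\t")
        if cols != _META_COLUMNS:
            raise ValueError(f"{path}: unexpected metadata header")
        for lineno, line in enumerate(fh, start=2):
            vals = dict(zip(cols, line.rstrip("\n").split("\t")))
            try:
                bil = _undot(vals["bilateral"])
                phen = Phenotype(
                    age_first_bc=_maybe_float(vals["age_first_bc"]),
                    age_second_bc=_maybe_float(vals["age_second_bc"]),
                    bilateral=None if bil is None else bil == "1",
                    er_status=_undot(vals["er_status"]),
                    her2_status=_undot(vals["her2_status"]),
                    n_fdr_breast=_maybe_int(vals["n_fdr_breast"]),
                    n_fdr_sdr_ovarian=_maybe_int(vals["n_fdr_sdr_ovarian"]),
                )
                out.append(SampleMeta(
                    sample_id=vals["sample_id"], n_reads=int(vals["n_reads"]),
                    mean_bait_coverage=float(vals["mean_bait_coverage"]),
                    brca_status=vals["brca_status"], phenotype=phen))
            except (ValueError, KeyError) as e:
                raise ValueError(f"{path}: line {lineno}: {e}") from e
    return out


def _maybe_float(s: str) -> float | None:
    v = _undot(s)
    return None if v is None else float(v)


def _maybe_int(s: str) -> int | None:
    v = _undot(s)
    return None if v is None else int(v)


# ---------------------------------------------------------------------------
# case-control report

REPORT_COLUMNS = ["Gene", "Case AC", "Case AN", "Case AF", "Control AC",
                  "Control AN", "Control AF", "OR", "CI low", "CI high",
                  "p-value"]


def _fmt_or(x: float) -> str:
    if math.isinf(x):
        return "inf"
    if math.isnan(x):
        return "NA"
    return f"{x:.2f}"


def write_report(results: "Iterable[CaseControlResult]",
                 path: str | Path) -> None:
    """Write the per-gene case-control table.

    Allele frequencies print to 5 decimals, OR and CI bounds to 2,
    p-values in scientific notation.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in results:
            t = r.table
            fh.write("\t".join([
                r.gene, str(t.case_ac), str(t.case_an), f"{r.case_af:.5f}",
                str(t.control_ac), str(t.control_an), f"{r.control_af:.5f}",
                _fmt_or(r.or_point), _fmt_or(r.ci[0]), _fmt_or(r.ci[1]),
                f"{r.p:.2E}",
            ]) + "\n")


def read_report(path: str | Path) -> pd.DataFrame:
    """Parse a written report back to its printed-precision values."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
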