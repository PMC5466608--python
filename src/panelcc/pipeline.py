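"""End-to-end orchestration: qc -> classify -> cnv -> tally -> test -> report.

A run consumes either freshly simulated inputs or files on disk, executes
the stages in fixed order, writes all stage outputs plus a machine-readable
run manifest (config hash, input digests, per-stage counts, versions), and
aborts on the first failing stage with the manifest recording what
completed. Stage counts telescope: each stage's input count equals the
previous stage's output count.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierConfig, classify_all
from .cnv import (classify_cnv, consensus_cnvs, read_cnv_calls,
                  write_cnv_calls)
from .cohort_io import (read_case_variants, read_control_table,
                        read_sample_meta, write_report)
from .panel import default_panel
from .sample_qc import (QCConfig, apply_sample_filters,
                        compute_cohort_metrics, filter_sites_and_genotypes)
from .simulate import (SimulatedCohort, SimulationConfig,
                       default_classifier_config, simulate_cohort)
from .stats import run_case_control
from .tally import tally_carriers, write_gene_tallies

log = logging.getLogger(__name__)

STAGES = ("load", "qc", "classify", "cnv", "tally", "test", "report")


@dataclass
class RunManifest:
    config_hash: str
    input_digests: dict[str, str]
    versions: dict[str, str]
    counts: dict[str, int] = field(default_factory=dict)
    stages_completed: list[str] = field(default_factory=list)
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    def check_telescoping(self) -> bool:
        c = self.counts
        ok = True
        if "variants_after_site_filter" in c:
            ok &= (c["variants_after_site_filter"]
                   == c["variants_after_sample_filter"]
                   - c["variants_removed_site_filter"])
        if "samples_in" in c and "samples_kept" in c:
            ok &= c["samples_kept"] == c["samples_in"] - c["samples_removed"]
        if "variants_classified" in c:
            ok &= (c["variants_classified"]
                   == c["variants_after_site_filter"])
        return bool(ok)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_yaml(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    unknown = set(cfg) - {"seed", "outdir", "simulate", "inputs", "qc",
                          "classify", "test", "an_exclusions"}
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ValueError("config needs a 'simulate' or an 'inputs' section")
    return cfg


def run_pipeline(config_path: str | Path) -> RunManifest:
    """Config-driven end-to-end run; see :func:`run_from_cohort`."""
    config_path = Path(config_path)
    cfg = _load_yaml(config_path)
    outdir = Path(cfg.get("outdir", config_path.parent / "panelcc_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = RunManifest(
        config_hash=_digest(config_path), input_digests={},
        versions={"panelcc": __version__},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))
    try:
        if "simulate" in cfg:
            sim_cfg = SimulationConfig(**(cfg["simulate"] or {}))
            cohort = simulate_cohort(sim_cfg, seed=seed)
            manifest.input_digests["simulate"] = f"seed={seed}"
        else:
            cohort = _load_inputs(cfg["inputs"], manifest)
        manifest.stages_completed.append("load")
        qc_cfg = QCConfig(**(cfg.get("qc") or {}))
        cls_cfg = (ClassifierConfig.from_yaml(cfg["classify"])
                   if isinstance(cfg.get("classify"), str)
                   else cohort.classifier_config)
        _run_stages(cohort, qc_cfg, cls_cfg, cfg, outdir, manifest)
    finally:
        manifest.write(outdir / "manifest.json")
    return manifest


def _load_inputs(inputs: dict, manifest: RunManifest) -> SimulatedCohort:
    panel = default_panel()
    paths = {k: Path(v) for k, v in inputs.items()}
    for k, p in paths.items():
        manifest.input_digests[k] = _digest(p)
    records = read_case_variants(paths["case_variants"], panel)
    control = read_control_table(paths["control_table"])
    calls_a = read_cnv_calls(paths["cnv_caller_a"])
    calls_b = read_cnv_calls(paths["cnv_caller_b"])
    meta = read_sample_meta(paths["sample_meta"])
    gdf = pd.read_csv(paths["qc_genotypes"], sep="\t")
    sample_ids = gdf["sample_id"].tolist()
    genotypes = gdf.drop(columns=["sample_id"]).to_numpy(dtype=np.int8)
    return SimulatedCohort(
        sample_ids=sample_ids, meta=meta, genotypes=genotypes,
        allele_freqs=None, x_marker_idx=None, records=records,
        control_table=control, cnv_calls_a=calls_a, cnv_calls_b=calls_b,
        control_cnvs=[], classifier_config=default_classifier_config(),
        panel=panel, truth=None)


def run_from_cohort(cohort: SimulatedCohort,
                    qc_cfg: QCConfig | None = None,
                    cls_cfg: ClassifierConfig | None = None,
                    threshold: float = 0.002,
                    or_method: str = "unconditional",
                    ci_method: str = "exact_conditional",
                    an_exclusions: int | None = None,
                    outdir: str | Path | None = None,
                    manifest: RunManifest | None = None):
    """Run qc -> classify -> cnv -> tally -> test on in-memory inputs.

    Returns ``(results, tallies, summary, manifest)``; stage outputs are
    written under ``outdir`` when given.
    """
    manifest = manifest or RunManifest(
        config_hash="in-memory", input_digests={},
        versions={"panelcc": __version__},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"))
    cfg = {"test": {"threshold": threshold, "or_method": or_method,
                    "ci_method": ci_method},
           "an_exclusions": an_exclusions}
    out = _run_stages(cohort, qc_cfg or QCConfig(),
                      cls_cfg or cohort.classifier_config, cfg,
                      Path(outdir) if outdir else None, manifest)
    return (*out, manifest)


def _run_stages(cohort: SimulatedCohort, qc_cfg: QCConfig,
                cls_cfg: ClassifierConfig, cfg: dict,
                outdir: Path | None, manifest: RunManifest):
    counts = manifest.counts

    # --- qc ---------------------------------------------------------------
    counts["samples_in"] = len(cohort.sample_ids)
    metrics = compute_cohort_metrics(
        cohort.genotypes, cohort.sample_ids, cohort.meta,
        allele_freqs=cohort.allele_freqs,
        x_marker_idx=cohort.x_marker_idx, cfg=qc_cfg)
    kept, ledger = apply_sample_filters(metrics, cohort.meta, qc_cfg)
    counts["samples_removed"] = len(ledger)
    counts["samples_kept"] = len(kept)

    counts["variants_in"] = len(cohort.records)
    records = [r for r in cohort.records if r.sample_id in kept]
    counts["variants_after_sample_filter"] = len(records)
    records, site_log = filter_sites_and_genotypes(records, qc_cfg)
    counts["variants_removed_site_filter"] = (
        site_log.n_allelic_ratio + site_log.n_call_rate)
    counts["variants_after_site_filter"] = \
        counts["variants_after_sample_filter"] \
        - counts["variants_removed_site_filter"]
    if outdir:
        ledger.to_csv(outdir / "exclusion_ledger.tsv", sep="\t", index=False)
    manifest.stages_completed.append("qc")

    # --- classify ---------------------------------------------------------
    calls = classify_all(records, cls_cfg)
    counts["variants_classified"] = len(calls)
    counts["mutations"] = sum(c.label in ("P", "LP") for c in calls.values())
    manifest.stages_completed.append("classify")

    # --- cnv --------------------------------------------------------------
    cnv_a = [c for c in cohort.cnv_calls_a if c.sample_id in kept]
    cnv_b = [c for c in cohort.cnv_calls_b if c.sample_id in kept]
    consensus = consensus_cnvs(cnv_a, cnv_b)
    cnv_classified = [(c, classify_cnv(c, cls_cfg)) for c in consensus]
    counts["cnv_calls_a"] = len(cnv_a)
    counts["cnv_calls_b"] = len(cnv_b)
    counts["cnv_consensus"] = len(consensus)
    counts["cnv_mutations"] = sum(cl.label in ("P", "LP")
                                  for _, cl in cnv_classified)
    if outdir:
        write_cnv_calls(consensus, outdir / "cnv_consensus.tsv")
    manifest.stages_completed.append("cnv")

    # --- tally ------------------------------------------------------------
    variant_calls = [(r, calls[(r.sample_id, r.variant_key)])
                     for r in records]
    tallies, groups, summary = tally_carriers(
        variant_calls, cnv_classified, cohort.panel,
        cohort_size=len(kept),
        an_exclusions=cfg.get("an_exclusions"))
    counts["unique_carriers"] = summary.n_unique_carriers
    counts["double_carriers"] = summary.n_double_carriers
    if outdir:
        write_gene_tallies(tallies, len(kept), outdir / "gene_tallies.tsv")
    manifest.stages_completed.append("tally")

    # --- test -------------------------------------------------------------
    test_cfg = cfg.get("test") or {}
    results = run_case_control(
        tallies, cohort.control_table,
        threshold=float(test_cfg.get("threshold", 0.002)),
        or_method=test_cfg.get("or_method", "unconditional"),
        ci_method=test_cfg.get("ci_method", "exact_conditional"))
    counts["case_control_rows"] = len(results)
    manifest.stages_completed.append("test")

    if outdir:
        write_report(results, outdir / "case_control_report.tsv")
        manifest.stages_completed.append("report")
    log.info("pipeline complete: %s", counts)
    return results, tallies, summary
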