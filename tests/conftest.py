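import pytest

from panelcc.cohort_io import VariantRecord
from panelcc.panel import default_panel
from panelcc.pipeline import run_from_cohort
from panelcc.simulate import SimulationConfig, simulate_cohort


def make_record(gene="ATM", consequence="missense", *, sample_id="S1",
                pos=1001, chrom=None, pop_af=None, clinvar=None,
                splice_offset=None, hgvs_c=None, hgvs_p=None,
                allelic_ratio=0.5, site_call_rate=0.95, ref="A", alt="T"):
    return VariantRecord(
        sample_id=sample_id, gene=gene, chrom=chrom or f"chr_{gene}",
        pos=pos, ref=ref, alt=alt, consequence=consequence,
        splice_offset=splice_offset, hgvs_c=hgvs_c, hgvs_p=hgvs_p,
        allelic_ratio=allelic_ratio, pop_af=pop_af or {},
        clinvar=clinvar or [], site_call_rate=site_call_rate)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def cohort():
    """Full-scale synthetic cohort under the planted study composition."""
    return simulate_cohort(seed=7)


@pytest.fixture(scope="session")
def pipeline_run(cohort):
    """End-to-end pipeline outputs on the session cohort."""
    results, tallies, summary, manifest = run_from_cohort(cohort)
    return {"results": results, "tallies": {t.gene: t for t in tallies},
            "summary": summary, "manifest": manifest, "cohort": cohort}


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort (600 samples) for determinism/round-trip checks."""
    cfg = SimulationConfig(n_samples=600)
    return simulate_cohort(cfg, seed=11)
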