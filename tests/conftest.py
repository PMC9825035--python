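import numpy as np
import pytest

from organellotype import synthdata as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_genome():
    genome, _ = sd.generate_reference(
        length=20000, repeat_spec=sd.RepeatSpec(), gene_density=0.1, seed=11
    )
    return genome


@pytest.fixture
def panel(small_genome, tmp_path):
    """A 400-accession clean panel (no missing data, no sequencing error)
    with one designated heteroplasmic site, emitted to a VCF."""
    sites = sd.design_sites(small_genome, 24, seed=21)
    spec = sd.paper_like_panel_spec(
        n_accessions=400,
        n_sites=24,
        n_haplotypes=10,
        seed=22,
        het_sites=[sd.HetSiteSpec(site_index=7, target_raf=0.66)],
        missing_rate=0.0,
        error_rate=0.0,
    )
    truth = sd.simulate_panel(spec, sites, small_genome)
    vcf = tmp_path / "panel.vcf"
    sd.emit_vcf(truth, vcf, seed=23)
    return truth, vcf
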