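import pytest
from hypothesis import HealthCheck, settings

from grfhap import proteins, variants
from grfhap.synthetic_data import (SimConfig, default_marker_defs,
                                   default_ssr_locus, simulate_panel,
                                   simulate_reference)

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cfg():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def model(cfg):
    return simulate_reference(cfg)


@pytest.fixture(scope="session")
def panel_truth(model, cfg):
    return simulate_panel(model, cfg)


@pytest.fixture(scope="session")
def truth(panel_truth):
    return panel_truth[1]


@pytest.fixture(scope="session")
def panel(panel_truth):
    return panel_truth[0]


@pytest.fixture(scope="session")
def ssr_locus(cfg):
    return default_ssr_locus(cfg)


@pytest.fixture(scope="session")
def marker_defs(cfg):
    return default_marker_defs(cfg)


@pytest.fixture(scope="session")
def haps(model, panel, ssr_locus):
    """Analyzed replayed panel (aligned, called, SSR-measured)."""
    return variants.analyze_panel(model, panel, ssr_locus=ssr_locus)


@pytest.fixture(scope="session")
def isoform_groups(haps, model):
    return proteins.group_isoforms(haps, model)


@pytest.fixture(scope="session")
def acc2allele(truth):
    return dict(zip(truth.accessions.accession, truth.accessions.allele))


@pytest.fixture(scope="session")
def hap_by_allele(haps, acc2allele):
    return {acc2allele[h.member_accessions[0]]: h for h in haps}
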