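import numpy as np
import pytest

from longqtl.panel import compute_grm
from longqtl.simulate import PanelDesign, TruthRecord, simulate_genotypes


@pytest.fixture(scope="session")
def tiny_design():
    """10 strains x 3 mice x 4 days, ~60 SNPs: oracle-comparison scale."""
    return PanelDesign(
        n_inbred=6,
        n_ri=4,
        n_founders=4,
        mice_per_strain=3,
        n_days=4,
        chrom_lengths=(("1", 3_000_000), ("2", 3_000_000)),
        snp_spacing=100_000,
        missing_rate=0.05,
        strains_per_cohort=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_panel(tiny_design):
    return simulate_genotypes(tiny_design)


@pytest.fixture(scope="session")
def tiny_grm(tiny_panel):
    return compute_grm(tiny_panel)


@pytest.fixture(scope="session")
def small_design():
    """20 strains x 4 mice x 6 days, complete genotypes: simulation-test scale."""
    return PanelDesign(
        n_inbred=12,
        n_ri=8,
        n_founders=6,
        mice_per_strain=4,
        n_days=6,
        chrom_lengths=(("1", 6_000_000), ("2", 6_000_000)),
        snp_spacing=100_000,
        missing_rate=0.0,
        strains_per_cohort=5,
        seed=23,
    )


@pytest.fixture(scope="session")
def small_panel(small_design):
    return simulate_genotypes(small_design)


@pytest.fixture(scope="session")
def small_grm(small_panel):
    return compute_grm(small_panel)


@pytest.fixture()
def default_truth():
    return TruthRecord()
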