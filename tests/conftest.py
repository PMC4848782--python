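import pytest

from celseq2pipe.barcode_design import design_barcodes
from celseq2pipe.simulate import SimConfig, simulate_run


@pytest.fixture(scope="session")
def paper_barcode_set():
    """The designed set under the published constraints (6 nt, distance 2, GC 33-67%, last base not T)."""
    return design_barcodes(6, 2, (33, 67), {"T"})


@pytest.fixture(scope="session")
def clean_sim(tmp_path_factory):
    """Small error-free run at full capture: the exact round-trip fixture."""
    config = SimConfig(
        n_cells=5,
        n_genes=100,
        n_spikeins=10,
        gene_mean_range=(0.5, 30.0),
        spike_mean_range=(1.0, 200.0),
        capture_efficiency=1.0,
        error_rate_barcode=0.0,
        error_rate_umi=0.0,
        seed=11,
    )
    return simulate_run(config, tmp_path_factory.mktemp("clean_sim"))
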