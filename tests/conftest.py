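import numpy as np
import pytest

from nadscape.core import samples_to_frame
from nadscape.simulate import SimConfig, make_genome, simulate_reads

TRIPLE_KO = "dxo1d_npy1d_rai1d"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """One modest default-condition simulation shared across read-level tests."""
    rng = np.random.default_rng(777)
    config = SimConfig(n_genes=60, reads_per_gene=1500)
    genome, annots, truths = make_genome(config, rng)
    aln, small, samples, manifest = simulate_reads(
        genome, annots, truths, config, TRIPLE_KO, rng)
    return {
        "config": config, "genome": genome, "annots": annots,
        "truths": truths, "alignments": aln, "small": small,
        "meta": samples_to_frame(samples), "manifest": manifest,
    }
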