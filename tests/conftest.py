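import numpy as np
import pytest

import cisgrammar as cg
from cisgrammar.library_design import enumerate_syn_elements
from cisgrammar.motifs import MotifModel


@pytest.fixture(scope="session")
def motifs():
    """The bundled synthetic O/S/K/E motif models."""
    return cg.default_motifs()


@pytest.fixture(scope="session")
def blocks():
    """The bundled synthetic 20-bp building blocks."""
    return cg.default_blocks()


@pytest.fixture(scope="session")
def syn_elements():
    return enumerate_syn_elements()


@pytest.fixture(scope="session")
def sharp_motif():
    """A sharply peaked toy motif (consensus frequency 0.97 per position)."""
    L = 8
    pfm = np.full((4, L), 1.0)
    consensus = [0, 3, 2, 1, 0, 0, 3, 2]  # ATGCAATG
    for j, b in enumerate(consensus):
        pfm[b, j] = 97.0
    return MotifModel("sharp", pfm)


@pytest.fixture(scope="session")
def sim_syn_dataset():
    """One simulated SYN experiment shared by the slower tests.

    Planted grammar truth -> experiment-scale barcode counts -> filtered counts.
    """
    from cisgrammar import mpra_quant as mq, simulate as sim

    els = enumerate_syn_elements()
    truth = sim.simulate_truth(els, sim.default_grammar(), seed=5)
    counts = sim.simulate_counts(truth.activity, sim.CountSimConfig(seed=6))
    filtered = mq.filter_barcodes(counts)
    return els, truth, counts, filtered
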