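import numpy as np
import pytest

import csrehmm as ch


@pytest.fixture(scope="session")
def toy_bins():
    """Two small chromosomes, 200-bp bins (10 + 5 bins)."""
    return ch.GenomeBins.from_chrom_sizes({"chr1": 2000, "chr2": 1000})


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study: planted specific states on a 10-Mb
    genome (T=50,000), run end to end through the real specificity
    transform, entropy init and batch EM."""
    cfg = ch.SimulationConfig()
    bins = cfg.bins()
    truth = ch.simulate_state_path(cfg)
    pms = ch.simulate_peak_matrices(cfg, truth)
    O = ch.stack_from_peaks(pms, cfg.s)
    init = ch.init_entropy(O, bins, cfg.n_states)
    params, trace = ch.em_fit(O, bins, init, mode="batch")
    return dict(cfg=cfg, bins=bins, truth=truth, peak_matrices=pms, O=O,
                init=init, params=params, trace=trace)


@pytest.fixture(scope="session")
def companions(default_sim):
    cfg, truth = default_sim["cfg"], default_sim["truth"]
    return ch.simulate_companions(cfg, truth)
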