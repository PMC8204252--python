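import pytest

from gliamotion import synth

from helpers import small_cfg


@pytest.fixture(scope="session")
def default_cell():
    """One simulated recording at the standard test scale (q = 0.1)."""
    cfg = small_cfg(11, turnover_q=0.1)
    stack, truth = synth.simulate(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def static_noisy_cell():
    """Motion-free cell with shot noise: the pipeline's noise-floor probe."""
    cfg = small_cfg(5, turnover_q=0.0)
    stack, truth = synth.simulate(cfg)
    return cfg, stack, truth
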