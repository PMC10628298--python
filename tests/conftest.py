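import numpy as np
import pytest

import lineagemem as lm


@pytest.fixture(scope="session")
def default_params() -> lm.TwoStateParams:
    """Drug-naive baseline: slow S->P, fast P->S, primed dividing at half rate."""
    return lm.TwoStateParams(r_s=0.2, r_p=0.1, p_on=1.0 / 354.0, p_off=1.0 / 12.6)


@pytest.fixture(scope="session")
def small_library() -> lm.BarcodeLibrary:
    return lm.gen_barcode_library(40, length=100, seed=11)


@pytest.fixture(scope="session")
def two_state_matrix():
    """A default-condition count matrix with known latent states."""
    cfg = lm.SynthConfig(n_cells=2000, n_genes=200, seed=5)
    rng = np.random.default_rng(7)
    states = {
        f"cell{i:05d}": ("P" if rng.random() < cfg.primed_fraction else "S")
        for i in range(cfg.n_cells)
    }
    return lm.gen_counts(states, cfg), states, cfg
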