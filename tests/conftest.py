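import numpy as np
import pandas as pd
import pytest

from cellquant import synthetic as syn


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """Tiny hand-checkable cohort: 6 patients, mixed events and censoring."""
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(6)],
        "expression": [0.1, 0.2, 0.3, 1.1, 1.2, 1.3],
        "time": [2.0, 4.0, 5.0, 1.0, 3.0, 6.0],
        "event": [1, 0, 1, 1, 1, 0],
    })


@pytest.fixture
def noiseless_phantom():
    spec = syn.InvasionPhantomSpec(invaded_fraction=0.5, noise_sd=0.0, seed=3)
    stack, true_frac = syn.gen_invasion_stack(spec)
    return spec, stack, true_frac
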