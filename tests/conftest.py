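import numpy as np
import pytest

from clonefate import ModelParams
from clonefate.progenitor_model import CloneRecord, simulate_clones_batch


@pytest.fixture
def balanced_params():
    """Homeostatic parameter set (delta = 0)."""
    return ModelParams(lambda_div=2.0, r=0.25, delta=0.0, gamma=3.5, mu=1.0)


@pytest.fixture
def expanding_params():
    """Fate-biased parameter set (delta > 0)."""
    return ModelParams(lambda_div=2.0, r=0.25, delta=0.4, gamma=3.5, mu=1.0)


def batch_records(params, timepoints, n_per_tp, seed, keep="at_least_one_basal"):
    """Clone records from the vectorized simulator, one seed per timepoint."""
    root = np.random.SeedSequence(seed)
    out = []
    for child, t in zip(root.spawn(len(timepoints)), timepoints):
        states = simulate_clones_batch(params, t, n_per_tp, seed=child)
        for p, d, s in states:
            m, n = int(p + d), int(s)
            if keep == "at_least_one_basal" and m < 1:
                continue
            if keep == "at_least_one_cell" and m + n < 1:
                continue
            out.append(CloneRecord("a", "c", float(t), m, n))
    return out
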