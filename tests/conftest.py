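import numpy as np
import pandas as pd
import pytest

from camoquant import Spectrum, gen_receptor_set
from camoquant.synthetic import flat_illuminant


@pytest.fixture(scope="session")
def receptors():
    """Default blue-tit-like Gaussian receptor fixture (uv/sw/mw/lw + dbl)."""
    return gen_receptor_set()


@pytest.fixture(scope="session")
def illuminant():
    return flat_illuminant()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_event_table(counts, check_split=None, n=100, end=72.0):
    """Event table with the given events-per-treatment ``counts`` dict and
    all remaining replicates censored at study end."""
    rows = []
    for trt, d in counts.items():
        if check_split is None:
            ev = [24.0] * (d // 3) + [48.0] * (d // 3) + [72.0] * (d - 2 * (d // 3))
        else:
            ev = [t for t, k in check_split[trt] for _ in range(k)]
        rows += [(trt, t, 1) for t in ev]
        rows += [(trt, end, 0)] * (n - d)
    return pd.DataFrame(rows, columns=["treatment", "time_h", "status"])
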