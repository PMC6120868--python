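import numpy as np
import pandas as pd
import pytest

from cagedyn import CountMatrix, SynthConfig
from cagedyn.simulate import simulate_timecourse


@pytest.fixture(scope="session")
def small_course():
    """A small two-agonist course with planted responders, shared across tests."""
    cfg = SynthConfig(n_promoters=400, n_tf_promoters=60, seed=42)
    counts, meta, truth = simulate_timecourse(cfg)
    return cfg, counts, meta, truth


@pytest.fixture()
def tiny_counts():
    df = pd.DataFrame(
        {"s1": [5, 0, 12], "s2": [9, 3, 1]},
        index=["p1@EGR1", "p2@EGR1", "p1@FOS"],
    )
    return CountMatrix(df.astype(np.int64))
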