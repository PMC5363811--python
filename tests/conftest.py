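import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import chronoluc as cl

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


def make_traceset(time_h, wells: dict, meta: dict | None = None) -> cl.TraceSet:
    """Build a TraceSet from arrays; meta maps well -> dict of metadata."""
    time_h = np.asarray(time_h, dtype=float)
    counts = pd.DataFrame({w: np.asarray(v, dtype=float) for w, v in wells.items()}, index=time_h)
    meta_df = pd.DataFrame.from_dict(meta or {w: {} for w in wells}, orient="index")
    meta_df.index.name = "well"
    return cl.TraceSet(time_h, counts, meta_df)


@pytest.fixture(scope="session")
def wt():
    return cl.get_preset("WT")


@pytest.fixture(scope="session")
def csl():
    return cl.get_preset("csl")


@pytest.fixture(scope="session")
def screen_reg():
    return cl.screen_regime()


@pytest.fixture(scope="session")
def cosine_ts():
    """Noise-free 24 h cosine around a positive offset, 0.5 h grid, 96 h."""
    t = np.arange(0, 96.5, 0.5)
    y = 10.0 + 4.0 * np.cos(2 * np.pi * t / 24.0)
    return make_traceset(t, {"w1": y})
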