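import numpy as np
import pandas as pd
import pytest

from cahow.signal_metrics import AccelTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(surge, sway, heave, rate=25.0, temp=None,
               start="2023-02-01 00:00:00"):
    surge = np.asarray(surge, dtype=float)
    return AccelTrace(
        start=pd.Timestamp(start),
        rate=rate,
        surge=surge,
        sway=np.asarray(sway, dtype=float),
        heave=np.asarray(heave, dtype=float),
        temperature=np.full(len(surge), 18.0) if temp is None else temp,
    )


@pytest.fixture
def trace_factory():
    return make_trace
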