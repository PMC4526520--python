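import numpy as np
import pandas as pd
import pytest

from cladeqpcr import synth


@pytest.fixture
def cp_summary_table() -> pd.DataFrame:
    """The field-survey Cp summary typed as the canonical table layout."""
    rows = [
        {"target": t, "depth_class": d, "mean": m, "sd": s, "n": n}
        for (t, d), (m, s, n) in synth.DEFAULT_SURVEY_CP.items()
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
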