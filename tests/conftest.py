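import datetime as dt

import pandas as pd
import pytest

import occudesign as od


@pytest.fixture(scope="session")
def paper_history():
    """One paper-like synthetic survey, binned and z-scored."""
    history, truth = od.simulate_binned(od.paper_like_scenario(), seed=11)
    return history, truth


@pytest.fixture(scope="session")
def m2_fit(paper_history):
    history, _ = paper_history
    return od.fit("M2", history, seed=0)


@pytest.fixture
def toy_frame():
    """Two sites, two occasions each, no covariates."""
    return pd.DataFrame(
        {
            "site": ["A", "A", "B", "B"],
            "method": ["acoustic"] * 4,
            "date": [dt.date(2021, 1, 1), dt.date(2021, 1, 2)] * 2,
            "y": [1, 0, 0, 0],
        }
    )


@pytest.fixture
def toy_history(toy_frame):
    return od.DetectionHistory(frame=toy_frame)
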