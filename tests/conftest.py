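import numpy as np
import pandas as pd
import pytest

from trialqc import TrialTable


def make_table(records):
    """Build a TrialTable from (participant, condition, trial, value) tuples."""
    return TrialTable(
        pd.DataFrame(records, columns=["participant", "condition", "trial", "value"])
    )


@pytest.fixture
def small_table():
    """Three participants, one condition, ragged trial counts."""
    return make_table(
        [
            ("P1", "A", 1, 0.5),
            ("P1", "A", 2, 1.5),
            ("P2", "A", 1, 2.0),
            ("P2", "A", 2, 2.5),
            ("P2", "A", 3, 3.0),
            ("P3", "A", 1, -1.0),
            ("P3", "A", 2, 0.0),
        ]
    )


@pytest.fixture
def constant_participants_table():
    """Each participant's trials are a distinct constant: split halves agree
    perfectly, so corrected reliability is exactly 1."""
    recs = []
    for i, c in enumerate([1.0, 2.0, 3.0, 4.0]):
        for t in range(1, 7):
            recs.append((f"P{i + 1}", "A", t, c))
    return make_table(recs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
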