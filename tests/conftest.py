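import numpy as np
import pandas as pd
import pytest

from cernaforge.io_formats import ClinicalTable, ExpressionMatrix
from cernaforge.pipeline import analyze_cohort
from cernaforge.synthetic import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated cohort at the default study conditions."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_analysis(default_cohort):
    """The core inference chain run once on the default cohort."""
    return analyze_cohort(default_cohort)


@pytest.fixture()
def tiny_matrix():
    """3 x 4 expression fixture with easily hand-checked values."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0], [2.0, 4.0, 6.0, 8.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix("mRNA", data)


def make_clinical(sample_ids, groups=None, times=None, events=None) -> ClinicalTable:
    n = len(sample_ids)
    if groups is None:
        groups = ["invasion" if i < n // 2 else "no_invasion" for i in range(n)]
    if times is None:
        times = np.linspace(10, 100, n)
    if events is None:
        events = [1] * n
    return ClinicalTable(
        pd.DataFrame(
            {"group": groups, "time": times, "event": events},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
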