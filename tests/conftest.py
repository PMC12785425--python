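import numpy as np
import pandas as pd
import pytest

from crsnet import MarkerPanel, SimConfig, impute_group_mean, simulate_cohort
from crsnet.behavior import score_behavior


@pytest.fixture(scope="session")
def panel() -> MarkerPanel:
    return MarkerPanel.default()


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (study design: 6 groups x 2 sexes x 8)."""
    return simulate_cohort(SimConfig(seed=12345))


@pytest.fixture(scope="session")
def expression(cohort):
    """The cohort's expression table, imputed and analysis-ready."""
    return impute_group_mean(cohort.expression)


@pytest.fixture(scope="session")
def behavior_scores(cohort):
    return score_behavior(cohort.weekly, cohort.traces)
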