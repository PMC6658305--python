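import numpy as np
import pandas as pd
import pytest

from pvfever import AnalysisConfig, generate_cohort
from pvfever.model import FeverStudy


@pytest.fixture(scope="session")
def default_cohort():
    """One moderate synthetic cohort shared across the suite."""
    return generate_cohort(2000, seed=42)


@pytest.fixture(scope="session")
def fitted_results(default_cohort):
    c = default_cohort
    return FeverStudy(c.events, c.readings, c.doses).fit()


@pytest.fixture(scope="session")
def loose_config():
    """Config that keeps every vaccine regardless of record count."""
    return AnalysisConfig(min_records_per_vaccine=1)


@pytest.fixture
def config():
    return AnalysisConfig()
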