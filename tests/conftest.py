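"""Shared fixtures: the study's scenario runs are expensive enough to
compute once per session and reuse across test modules."""

import pytest

from phthalpbpk import run_paper_scenario
from phthalpbpk.validation import run_koch_single_dose


@pytest.fixture(scope="session")
def oral_2day():
    """Two days of the scheduled oral diet (0.5/0.8/0.65 mg at 8/12/18 h)."""
    return run_paper_scenario("oral", days=2)


@pytest.fixture(scope="session")
def oral_5day():
    return run_paper_scenario("oral", days=5)


@pytest.fixture(scope="session")
def dermal_5day():
    """120 h of continuous 0.68 mg/h dermal exposure."""
    return run_paper_scenario("dermal", days=5)


@pytest.fixture(scope="session")
def inhalation_5day():
    """120 h of continuous 0.53 mg/h inhalation exposure."""
    return run_paper_scenario("inhalation", days=5)


@pytest.fixture(scope="session")
def koch_run():
    """Single 48.1 mg oral dose, 75 kg subject, 72 h."""
    return run_koch_single_dose()
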