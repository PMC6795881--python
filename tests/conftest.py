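import numpy as np
import pytest
from hypothesis import settings

from megaim.behavioral_metrics import summarize_blocks
from megaim.synthetic_data import ExperimentDesign, ProfileDistribution, simulate_experiment
from megaim.task_model import GainFunction

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def gf():
    return GainFunction()


@pytest.fixture(scope="session")
def cohort(gf):
    """One default synthetic cohort (21 participants x 700 trials), scored."""
    trials, profiles = simulate_experiment(master_seed=7, gf=gf)
    return trials, profiles


@pytest.fixture(scope="session")
def cohort_summaries(cohort, gf):
    trials, _ = cohort
    return summarize_blocks(trials, gf)


@pytest.fixture(scope="session")
def small_cohort(gf):
    """A 2+2-participant cohort for fast structural/round-trip tests."""
    design = ExperimentDesign(n_display=2, n_no_display=2)
    return simulate_experiment(design, ProfileDistribution(), master_seed=3, gf=gf)
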