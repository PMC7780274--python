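import numpy as np
import pytest

from mwcst import score_cohort, simulate_cohort
from mwcst.task_model import TrialRecord


def records_from(responses, patient_id="p1", feedback=None):
    """Build TrialRecords from a sequence of response dimensions."""
    fb = feedback if feedback is not None else [None] * len(responses)
    return [
        TrialRecord(patient_id=patient_id, trial_index=i + 1,
                    response_dim=r, feedback=f)
        for i, (r, f) in enumerate(zip(responses, fb))
    ]


@pytest.fixture(scope="session")
def sim_cohort():
    """Default-calibration 128-patient cohort, fixed seed."""
    return simulate_cohort(rng=11)


@pytest.fixture(scope="session")
def sim_scores(sim_cohort):
    return score_cohort(sim_cohort, 48)
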