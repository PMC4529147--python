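import numpy as np
import pytest

from stressmeta import CohortSpec, ObserverParams, StaircaseConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_observer():
    return ObserverParams(sensitivity_scale=10.0)


@pytest.fixture
def staircase_cfg():
    return StaircaseConfig()


@pytest.fixture
def small_cohort_spec():
    """Cheap cohort for pipeline-level tests."""
    return CohortSpec(n_per_group=3, n_trials_main=80, seed=7)


def pairwise_auc(correct, confidence):
    """Independent oracle: P(conf_correct > conf_incorrect) + 0.5 P(tie)."""
    correct = np.asarray(correct, dtype=bool)
    confidence = np.asarray(confidence, dtype=float)
    c = confidence[correct]
    i = confidence[~correct]
    gt = (c[:, None] > i[None, :]).mean()
    tie = (c[:, None] == i[None, :]).mean()
    return gt + 0.5 * tie
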