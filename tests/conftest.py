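import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from convoscreen import outcomes
from convoscreen.synthetic_cohort import CohortConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort: short interviews, low-dimensional streams."""
    cfg = CohortConfig(
        n_participants=14,
        seed=21,
        effect_size=1.0,
        length_range_min=(4.0, 7.0),
        modality_dims={"emotion_aus": 6, "bpm": 1, "sentiment": 5,
                       "text_embedding": 32},
        sampling_rates={"emotion_aus": 1.0, "sentiment": 1.0 / 15.0},
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_labels(small_cohort):
    labs = outcomes.labels_for_cohort(small_cohort)
    return {task: {pid: l[task] for pid, l in labs.items()}
            for task in outcomes.OUTCOMES}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
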