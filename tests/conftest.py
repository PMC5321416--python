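import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_study():
    """A hand-built 2-participant dataset with known ratings."""
    from painprior.trial_model import COLUMNS, StudyDataset
    import pandas as pd

    rows = []
    for pid, cond_ratings, test_ratings in (
        ("A", [(1, "doctor", 64, 10.0), (2, "doctor", 256, 60.0),
               (3, "pharmacy", 256, 55.0), (4, "pharmacy", 256, 57.0)],
         [(1, "doctor", 80.0), (2, "pharmacy", 85.0), (3, "control", 95.0)]),
        ("B", [(1, "pharmacy", 256, 58.0), (2, "doctor", 64, 12.0),
               (3, "doctor", 256, 62.0), (4, "pharmacy", 256, 60.0)],
         [(1, "doctor", 82.0), (2, "pharmacy", 88.0), (3, "control", 93.0)]),
    ):
        for t, choice, w, r in cond_ratings:
            rows.append(dict(participant_id=pid, session="conditioning",
                             trial_index=t, choice=choice, stimulus_weight=w,
                             pain_rating=r, cost=2.0 if choice == "doctor" else 1.0))
        for t, choice, r in test_ratings:
            rows.append(dict(participant_id=pid, session="test", trial_index=t,
                             choice=choice, stimulus_weight=512,
                             pain_rating=r, cost=0.0))
    return StudyDataset(pd.DataFrame(rows, columns=COLUMNS))
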