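import numpy as np
import pytest
from hypothesis import settings

import beatsync as bs
from beatsync import pipeline

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240112)


@pytest.fixture(scope="session")
def study():
    """Default synthetic study: trials table, ground truth, trial objects."""
    trials_df, truth_df = bs.generate_study(rng_seed=7)
    trials = []
    for (sid, tempo, idx), rows in trials_df.groupby(
        ["subject_id", "tempo_bpm", "trial_index"], sort=True
    ):
        rows = rows.sort_values("event_index")
        trials.append(
            bs.MovementTrial(
                subject_id=str(sid),
                group=str(rows["group"].iloc[0]),
                tempo_bpm=float(tempo),
                trial_index=int(idx),
                event_times_s=tuple(rows["time_s"]),
            )
        )
    return trials_df, truth_df, trials


@pytest.fixture(scope="session")
def study_summaries(study):
    _, _, trials = study
    return pipeline.trial_summaries(trials)
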