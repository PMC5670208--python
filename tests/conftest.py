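import numpy as np
import pandas as pd
import pytest

from cb1pipe import (BloodProfile, build_basis, meppep_frame_schedule,
                     synthetic_trues_rate)


@pytest.fixture(scope="session")
def profile():
    return BloodProfile()


@pytest.fixture(scope="session")
def input_fn(profile):
    return profile.input_function()


@pytest.fixture(scope="session")
def whole_blood(profile):
    return profile.whole_blood_curve()


@pytest.fixture(scope="session")
def schedule(input_fn):
    base = meppep_frame_schedule()
    return meppep_frame_schedule(synthetic_trues_rate(base, input_fn))


@pytest.fixture(scope="session")
def basis(input_fn, schedule, whole_blood):
    return build_basis(input_fn, schedule, whole_blood=whole_blood)


@pytest.fixture()
def stimulus_table():
    n = 60
    return pd.DataFrame({
        "onset_s": 10.0 + 12.0 * np.arange(n),
        "valence": ["fearful" if i % 2 == 0 else "neutral" for i in range(n)],
    })
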