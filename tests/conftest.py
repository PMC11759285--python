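import numpy as np
import pytest

import sfi_timing as st
from sfi_timing.simulate import Trial


def make_trial(presses, fi=None, block=1, idx=1):
    """Build a Trial directly from a press list (last press = reward)."""
    p = np.asarray(presses, dtype=float)
    if fi is None:
        fi = float(p[-1])
    return Trial(
        block_index=block, trial_index_in_block=idx, fi_duration=float(fi),
        press_times=p, reward_time=float(p[-1]),
    )


@pytest.fixture(scope="session")
def one_shot_cohort():
    """Default one-shot cohort (w=0.2, alpha=1), 12 subjects, fixed seed."""
    return st.simulate_cohort(
        st.Protocol(), st.PRESETS["rat_fast"], n_subjects=12, master_seed=3)


@pytest.fixture(scope="session")
def one_shot_table(one_shot_cohort):
    return st.estimate_all(one_shot_cohort)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """One-shot noiseless cohort (w=0) used for scaling checks."""
    params = st.AgentParams(weber_cv=0.0, learning_rate=1.0)
    return st.simulate_cohort(st.Protocol(), params, n_subjects=8, master_seed=11)
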