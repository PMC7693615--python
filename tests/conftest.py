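import numpy as np
import pandas as pd
import pytest

from fnirspipe import simulate as sim
from fnirspipe.montage import default_montage


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture()
def sim_config():
    return sim.SimulationConfig(n_per_group=2, seed=11)


@pytest.fixture()
def participant():
    return sim.Participant("EG01", "experimental", age_years=69.0, mmse=29.0)


def make_trials(n_blocks=2, trials_per_block=15, condition="2-back", rt_ms=800.0,
                correct=True, participant_id="P1", time_point="pre",
                group="experimental"):
    """Hand-built trial table: all targets in the first five trials."""
    rows = []
    for b in range(1, n_blocks + 1):
        for t in range(1, trials_per_block + 1):
            is_target = t <= 5
            key = ("match" if is_target else "non-match")
            resp = key if correct else ("non-match" if is_target else "match")
            rows.append({
                "participant_id": participant_id, "group": group,
                "time_point": time_point, "condition": condition, "block": b,
                "trial": t, "onset_s": 3.0 * (t - 1), "is_target": is_target,
                "response": resp, "rt_ms": rt_ms,
            })
    return pd.DataFrame(rows)


@pytest.fixture()
def trial_table():
    return make_trials()
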