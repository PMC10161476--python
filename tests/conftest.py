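import numpy as np
import pytest

from autonomic_beta import betacell, hrv
from autonomic_beta.synthcohort import GLUCOSE_TEMPLATES


@pytest.fixture(scope="session")
def ngm_kinetics():
    return betacell.cpeptide_kinetics(age=60.0, sex="M", bmi=26.0, gms="NGM")


@pytest.fixture(scope="session")
def ngm_glucose():
    return GLUCOSE_TEMPLATES["NGM"].copy()


def make_nn(nn_ms, onset_s=None, segment_s=300.0):
    """Build an NNSeries directly from interval values (single contiguous run
    unless onsets say otherwise)."""
    nn_ms = np.asarray(nn_ms, dtype=float)
    if onset_s is None:
        onset_s = np.concatenate([[0.0], np.cumsum(nn_ms[:-1]) / 1000.0])
    onset_s = np.asarray(onset_s, dtype=float)
    return hrv.NNSeries(
        nn_ms=nn_ms,
        onset_time_s=onset_s,
        run_id=np.zeros(nn_ms.size, dtype=int),
        segment_index=np.floor_divide(onset_s, segment_s).astype(int),
        effective_duration_h=float(nn_ms.sum()) / 3.6e6,
    )


@pytest.fixture
def worked_nn():
    """The five-interval worked series used for the hand-computed goldens."""
    return make_nn([800.0, 810.0, 790.0, 850.0, 800.0])
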