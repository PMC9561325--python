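import numpy as np
import pytest

import deepmpm as dm
from deepmpm.ehr_data import EncodedSequence
from deepmpm.model import DeepMPMParams


@pytest.fixture(scope="session")
def fixture_cohort():
    return dm.make_fixture_cohort()


@pytest.fixture(scope="session")
def small_cohort():
    """Small cleaned synthetic cohort shared by fast tests."""
    cfg = dm.SynthConfig(n_patients=120, seed=5)
    return dm.clean_cohort(dm.generate_cohort(cfg))


@pytest.fixture(scope="session")
def encoded(small_cohort):
    vd = dm.build_vocab(small_cohort, "diagnosis")
    vg = dm.build_vocab(small_cohort, "drg")
    seqs = dm.encode_sequences(small_cohort, vd, vg)
    return vd, vg, seqs


def make_toy_sequence(patient_id, rng, n_dx=6, n_drg=3, T=3, died=False):
    """Hand-sized encoded sequence with consistent day offsets."""
    x = np.zeros((T, n_dx))
    p = np.zeros((T, n_drg))
    for t in range(T):
        x[t, rng.choice(n_dx, size=2, replace=False)] = 1.0
        p[t, rng.integers(n_drg)] = 1.0
    admit = np.array([0.0, 20.0, 45.0])[:T]
    disch = np.array([5.0, 28.0, 50.0])[:T]
    delta_prev = np.concatenate([[0.0], admit[1:] - disch[:-1]])
    y = np.zeros(T)
    if died:
        y[-1] = 1.0
    return EncodedSequence(
        patient_id=patient_id, x=x, p=p,
        m=np.array([1.0, 2.0, 1.0])[:T],
        delta_prev=delta_prev,
        delta_to_last=disch[-1] - admit,
        y=y, mask=np.ones(T, dtype=bool),
        admit_day=admit, discharge_day=disch,
    )


@pytest.fixture
def toy_batch():
    rng = np.random.default_rng(42)
    return [make_toy_sequence("T1", rng, died=True),
            make_toy_sequence("T2", rng, died=False)]


@pytest.fixture
def toy_params():
    rng = np.random.default_rng(7)
    return DeepMPMParams.init(6, 3, d=5, hidden_alpha=6, hidden_beta=7,
                              rng=rng, scale=0.3)
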