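import numpy as np
import pytest

import msmflux as mf

TWO_STATE_T = np.array([[0.9, 0.1], [0.2, 0.8]])
THREE_STATE_T = np.array([[0.9, 0.1, 0.0], [0.1, 0.8, 0.1], [0.0, 0.1, 0.9]])


@pytest.fixture(scope="session")
def two_state_dtraj():
    """1e5 steps sampled exactly from the 2-state reference chain."""
    return mf.sample_markov_chain(TWO_STATE_T, 100_000, start=0, seed=123)


@pytest.fixture(scope="session")
def small_planted_dataset():
    """A reduced dihedral-like dataset with 3 planted metastable states."""
    return mf.emulate_dihedral_dataset(
        n_traj=5, n_frames=1500, n_features=24, n_metastable=3, seed=42
    )


@pytest.fixture(scope="session")
def small_pipeline_inputs(small_planted_dataset):
    ds = small_planted_dataset
    emb = [mf.sincos_embed(t) for t in ds.trajectories]
    tica = mf.TICA(emb, lag=10, dim=3).fit()
    proj = [tica.transform(t) for t in emb]
    return ds, proj


def best_permutation_agreement(true_labels, pred_labels, n_states):
    """Fraction of frames matching under the best label permutation."""
    from scipy.optimize import linear_sum_assignment

    conf = np.zeros((n_states, n_states))
    np.add.at(conf, (np.asarray(true_labels), np.asarray(pred_labels)), 1)
    r, c = linear_sum_assignment(-conf)
    return conf[r, c].sum() / len(true_labels)
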