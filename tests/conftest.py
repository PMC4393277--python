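import numpy as np
import pytest

from irmap.dictfit import build_dictionary
from irmap.radial import golden_angle_trajectory
from irmap.relaxometry import SequenceParams
from irmap.simulate import (
    make_vial_phantom,
    simulate_coil_sensitivities,
    simulate_radial_irll,
)


@pytest.fixture(scope="session")
def seq():
    """Paper-protocol sequence timing (TR 6 ms, TE 2.5 ms, alpha 7 deg)."""
    return SequenceParams()


@pytest.fixture(scope="session")
def small_seq():
    return SequenceParams(n_projections=200, n_readout=32)


@pytest.fixture(scope="session")
def frame_times_small(small_seq):
    return small_seq.te + small_seq.tr * np.arange(small_seq.n_projections)


@pytest.fixture(scope="session")
def small_dictionary(small_seq, frame_times_small):
    return build_dictionary(small_seq, frame_times_small)


@pytest.fixture(scope="session")
def small_acquisition(small_seq):
    """Noisy 2-coil acquisition of a 3-vial phantom at 32x32 / 200 spokes."""
    _, truth = make_vial_phantom(32, t1_values=(300.0, 900.0, 1800.0))
    sens = simulate_coil_sensitivities(32, 2, seed=7)
    traj = golden_angle_trajectory(200, 32, small_seq)
    acq = simulate_radial_irll(truth, sens, traj, small_seq, noise_sigma=0.002, seed=3)
    return acq, truth
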