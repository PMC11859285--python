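import numpy as np
import pytest

import sprintgnss as sg


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free 20-step sprint with ground truth (shared, read-only)."""
    return sg.simulate_sprint(sg.preset("clean_unit_test", seed=1))


@pytest.fixture(scope="session")
def clean_kin(clean_sim):
    return sg.build_kinematics(sg.to_local_enu(clean_sim.traj))


@pytest.fixture()
def flat_kin():
    """A stationary, noise-free kinematic series for degenerate-input tests."""
    n = 500
    t = np.arange(n) / 100.0
    zeros = np.zeros(n)
    return sg.KinematicSeries(
        t=t, u_f=zeros.copy(), v_u=zeros.copy(), e_f=zeros.copy(),
        n_f=zeros.copy(), cum_dist=zeros.copy(),
        status=np.full(n, "FIX", dtype=object), rate=100.0)


def make_kin(t, u, e=None, n=None, rate=100.0, status=None):
    """Assemble a KinematicSeries from raw arrays (no filtering)."""
    t = np.asarray(t, dtype=float)
    u = np.asarray(u, dtype=float)
    e = np.zeros_like(t) if e is None else np.asarray(e, dtype=float)
    n = np.zeros_like(t) if n is None else np.asarray(n, dtype=float)
    status = (np.full(len(t), "FIX", dtype=object)
              if status is None else np.asarray(status, dtype=object))
    return sg.KinematicSeries(
        t=t, u_f=u, v_u=sg.differentiate(u, rate), e_f=e, n_f=n,
        cum_dist=sg.cumulative_distance(e, n), status=status, rate=rate)
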