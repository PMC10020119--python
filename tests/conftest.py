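import numpy as np
import pytest

from mesohist import DiffusionProtocol, PhantomConfig, SignalVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def protocol():
    """The standard three-shell, six-direction acquisition."""
    return DiffusionProtocol.three_shell()


def random_spd_tensors(rng, n, lam_range=(1e-4, 2.5e-3)):
    """Random SPD 3×3 tensors via random rotations of random eigenvalues."""
    from scipy.stats import special_ortho_group

    lam = rng.uniform(*lam_range, size=(n, 3))
    R = special_ortho_group.rvs(3, size=n, random_state=np.random.RandomState(
        rng.integers(2**31)))
    if n == 1:
        R = R[None]
    return np.einsum("nij,nj,nkj->nik", R, lam, R)


def forward_signals(tensors, protocol, s0=1000.0):
    """Independent forward simulation of the exponential tensor model.

    Used as the oracle for round-trip tests: S = s0 · exp(−b gᵀDg), written
    directly from the model definition without reusing the fitting code.
    """
    quad = np.einsum("mi,nij,mj->nm", protocol.directions, tensors,
                     protocol.directions)
    return s0 * np.exp(-protocol.b_values[None, :] * quad)


@pytest.fixture
def small_phantom_config():
    return PhantomConfig(n_cells=(12, 12), density_max=40.0, seed=7)


def signal_volume_from_tensors(tensors, protocol, s0=1000.0):
    """Pack per-tensor signals into a (n, 1, 1, m) SignalVolume."""
    S = forward_signals(tensors, protocol, s0)
    return SignalVolume(S[:, None, None, :], 200.0, protocol)
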