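import numpy as np
import pytest

from aslhemo.signal_models import AcquisitionParams, BloodProperties


@pytest.fixture(scope="session")
def multi_acq():
    return AcquisitionParams.multi_ti_pasl()


@pytest.fixture(scope="session")
def single_acq():
    return AcquisitionParams.single_ti_pcasl()


@pytest.fixture(scope="session")
def blood_sca():
    """Blood with the patient-typical T1 (long T1 from low hematocrit)."""
    return BloodProperties(t1_blood=1.99)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def simulate_voxels(cbf, bat, acq, blood, m0=100.0, noise_sd=0.0, rng=None):
    """Forward-simulate a (n_vox, 1, 1, n_ti) series for given truths."""
    from aslhemo.signal_models import pasl_kinetic_signal
    cbf = np.atleast_1d(np.asarray(cbf, dtype=float))
    bat = np.atleast_1d(np.asarray(bat, dtype=float))
    times = np.asarray(acq.inflow_times)
    sig = np.stack([np.asarray(pasl_kinetic_signal(t, cbf, bat, acq, blood,
                                                   m0_tissue=m0))
                    for t in times], axis=-1)
    if noise_sd > 0:
        sig = sig + rng.normal(0, noise_sd, sig.shape)
    n = cbf.size
    series = sig.reshape(n, 1, 1, times.size)
    m0_vol = np.full((n, 1, 1), float(m0))
    mask = np.ones((n, 1, 1), dtype=bool)
    return series, m0_vol, mask
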