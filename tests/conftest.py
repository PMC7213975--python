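import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config():
    from statephys.pipeline import RunConfig

    return RunConfig()


@pytest.fixture(scope="session")
def eight_bout_session():
    """The reference synthetic wheel session: 600 s, 8 bouts, noise 0.3."""
    from statephys.simulate import gen_wheel_trace, random_bout_spec

    spec = random_bout_spec(600.0, 8, seed=7)
    wheel, bouts = gen_wheel_trace(600.0, spec, noise_sd_cm_s=0.3, seed=7)
    return wheel, bouts, spec


@pytest.fixture(scope="session")
def quiet_lfp_psd():
    """PSD of unit-variance white noise over a long clean epoch."""
    from statephys.spectral import LFPSignal, compute_psd

    rng = np.random.default_rng(12)
    lfp = LFPSignal(fs=1000.0, samples=rng.normal(0.0, 1.0, 120_000))
    return compute_psd(lfp, [(0.0, 120.0)])
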