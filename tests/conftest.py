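import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tripecg.synth import NO_NOISE, NoiseSpec, make_template, synth_record

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_template():
    """Default sinus template: PR 160, QRS 90, QT 380 ms."""
    return make_template(pr=160, qrs=90, qt=380)


@pytest.fixture(scope="session")
def clean_record(base_template):
    """Noiseless, jitterless 10-s record at RR 1000 ms (10 beats)."""
    return synth_record(base_template, mean_rr=1000.0, seed=1, record_id="clean")


@pytest.fixture(scope="session")
def noisy_record(base_template):
    """Same template with 20 µV broadband noise and mild RR jitter."""
    return synth_record(
        base_template, mean_rr=900.0, rr_jitter_sd=20.0,
        noise=NoiseSpec(broadband_sd_uv=20.0), seed=2, record_id="noisy",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
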