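import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def swim_sim():
    """One responsive swimming-worm simulation with two light pulses."""
    from wormpulse.protocols import LightSchedule
    from wormpulse.simulate import ContractionModel, simulate_video, swim_preset

    schedule = LightSchedule.from_intervals([(5, 6), (14, 15)], 20.0)
    sim = simulate_video(
        swim_preset(), ContractionModel(), schedule, 10.0, 20.0, seed=7
    )
    return sim


@pytest.fixture(scope="session")
def crawl_frame():
    """One noisy solid-media frame plus its ground-truth mask."""
    from wormpulse.simulate import crawl_preset, render_frame, worm_midline

    model = crawl_preset()
    midline = worm_midline(model, phase=0.7, curl=0.4)
    rng = np.random.default_rng(11)
    image, (mask,) = render_frame(
        [midline], [model], (300, 300), noise_sd=0.02, rng=rng
    )
    return image, mask, midline
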