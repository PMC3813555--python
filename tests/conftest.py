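import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from batmri.dixon import compute_fat_fraction, separate_water_fat, signal_mask  # noqa: E402
from batmri.phantom import (  # noqa: E402
    make_torso_phantom,
    make_vial_phantom,
    torso_phantom_spec,
    vial_phantom_spec,
)

#: Scene scale used for fast unit tests (grid ~70 x 53 x 35).
SMALL_SCALE = 0.55


@pytest.fixture(scope="session")
def vial():
    """Default two-vial ex-vivo phantom with mild noise."""
    echoes, truth = make_vial_phantom(vial_phantom_spec(rng_seed=11))
    return echoes, truth


@pytest.fixture(scope="session")
def torso_small():
    """Scaled-down torso phantom plus its separated/derived volumes."""
    spec = torso_phantom_spec(scale=SMALL_SCALE, rng_seed=7)
    echoes, truth, seeds = make_torso_phantom(spec)
    wf = separate_water_fat(echoes, dominance=truth.recon_dominance)
    ff = compute_fat_fraction(wf)
    sig = signal_mask(wf)
    return {"echoes": echoes, "truth": truth, "seeds": seeds, "wf": wf, "ff": ff, "sig": sig}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
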