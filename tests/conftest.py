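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

from dbtcad import PhantomConfig, generate_phantom  # noqa: E402


@pytest.fixture(scope="session")
def default_phantom():
    """One standard phantom volume with truth, shared across tests."""
    return generate_phantom(PhantomConfig(rng_seed=7))


@pytest.fixture(scope="session")
def clean_blob_line_phantom():
    """Flat-background phantom with a single MC blob and one axis-aligned
    line distractor: the geometry fixture for shape discrimination."""
    cfg = PhantomConfig(
        background="flat",
        n_clusters=1,
        mcs_per_cluster=(1, 1),
        n_line_distractors=1,
        n_plane_distractors=0,
        line_orientations_deg=(0.0,),
        rng_seed=3,
    )
    return cfg, generate_phantom(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
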