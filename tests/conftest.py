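import numpy as np
import pytest

import octseg as o


@pytest.fixture(scope="session")
def small_spec() -> o.PhantomSpec:
    """Compact phantom spec used by most unit tests (fast to render)."""
    return o.PhantomSpec(image_size_px=256, lumen_radius_px=70.0,
                         wall_thickness_px=50.0, n_frames=6,
                         strut_count_mean=7.0, strut_count_sd=1.0, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return o.generate_pullback(small_spec)


@pytest.fixture(scope="session")
def small_run(small_spec, small_phantom):
    """Full pipeline output on the small clean phantom (shared, read-only)."""
    pb, _truth = small_phantom
    segs, _ = o.run_pullback(pb, o.run_config_for(small_spec))
    return segs


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
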