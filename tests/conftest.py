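import numpy as np
import pytest

from spherovia.synth import (
    SyntheticStudySpec,
    generate_study,
    render_spheroid,
    viability_to_morphology,
)


@pytest.fixture(scope="session")
def render_batch():
    """Factory: n rendered spheroids with viabilities, deterministic seeds."""

    def _make(n, seed0=1000, v_low=0.0, v_high=1.2, image_size=96):
        rng = np.random.default_rng(seed0)
        out = []
        for i in range(n):
            v = float(rng.uniform(v_low, v_high))
            params = viability_to_morphology(v, seed0 + i)
            img, mask = render_spheroid(params, image_size, seed0 + 50000 + i)
            out.append((v, img, mask))
        return out

    return _make


@pytest.fixture(scope="session")
def small_study():
    """One 48-well synthetic study with in-memory images and ground truth."""
    spec = SyntheticStudySpec(study_id="S1", wells_per_plate=48,
                              control_fraction=0.25, seed=7, day=5)
    return generate_study(spec)


@pytest.fixture()
def disk_mask():
    """Factory for a discrete disk mask of a given radius."""

    def _make(radius, frame=None):
        frame = frame or int(np.ceil(2.6 * radius))
        c = (frame - 1) / 2
        yy, xx = np.mgrid[0:frame, 0:frame]
        return np.hypot(xx - c, yy - c) <= radius

    return _make
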