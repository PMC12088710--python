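import dataclasses

import numpy as np
import pytest

import octquant as oq
from octquant.phantom import DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def default_phantom():
    """Representative phantom frame with its analytic metrics."""
    frame, truth = oq.render_phantom(oq.default_phantom_spec())
    return frame, truth


@pytest.fixture(scope="session")
def default_profiles(default_phantom):
    frame, _ = default_phantom
    origin = oq.lumen_centroid(frame)
    return oq.cast_rays(frame, origin), origin


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_spec(**overrides):
    """Small-phantom spec builder used across test modules."""
    base = dict(
        geometry=DEFAULT_GEOMETRY,
        lumen_center_px=(447.5, 447.5),
        lumen_radius_mm=1.0,
        intima_thickness_mm=0.25,
        media_thickness_mm=0.15,
        sectors=[],
    )
    base.update(overrides)
    return oq.PhantomSpec(**base)
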