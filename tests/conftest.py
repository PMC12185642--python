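import numpy as np
import pytest

from graftflow import fixtures as fx


@pytest.fixture(scope="session")
def coarse_cylinder():
    """Small cylinder for fast structural tests."""
    spec = fx.CylinderFixtureSpec(n_radial=3, n_theta=12, n_axial=4)
    vol, wall = fx.make_cylinder_mesh(spec)
    return spec, vol, wall


@pytest.fixture(scope="session")
def refined_cylinder():
    """Refined cylinder: polygonal-section volume/area within 1% of analytic."""
    spec = fx.CylinderFixtureSpec(n_radial=6, n_theta=32, n_axial=10)
    vol, wall = fx.make_cylinder_mesh(spec)
    return spec, vol, wall


@pytest.fixture(scope="session")
def refined_annulus():
    """Flat annulus refined enough for ~2% divergence error on the 1/r field."""
    return fx.make_annulus_surface(0.5, 1.5, n_radial=32, n_theta=128)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
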