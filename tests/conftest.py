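import logging

import numpy as np
import pytest

from nadder.geometry import Curve3D, resample_curve

logging.getLogger("nadder").setLevel(logging.ERROR)


@pytest.fixture
def straight_line():
    """101-point straight segment along x, 1 um spacing."""
    t = np.linspace(0.0, 100.0, 101)
    return Curve3D(np.column_stack([t, np.zeros_like(t), np.zeros_like(t)]))


@pytest.fixture
def circle_r2():
    """Planar circle of radius 2 um, densely sampled (kappa = 0.5)."""
    th = np.linspace(0, 2 * np.pi, 400, endpoint=False)
    return Curve3D(np.column_stack([2 * np.cos(th), 2 * np.sin(th),
                                    np.zeros_like(th)]))


@pytest.fixture
def helix_unit():
    """Circular helix a = b = 1 (kappa = tau = 0.5), densely sampled."""
    t = np.linspace(0, 12 * np.pi, 2000)
    return Curve3D(np.column_stack([np.cos(t), np.sin(t), t]))


@pytest.fixture
def planar_spiral():
    """Archimedean spiral in the z = 0 plane, resampled at 1 um."""
    th = np.linspace(0.5, 6 * np.pi, 3000)
    r = 3 + 2 * th
    spiral = Curve3D(np.column_stack([r * np.cos(th), r * np.sin(th),
                                      np.zeros_like(th)]))
    return resample_curve(spiral, 1.0)


def rigid_motion(rng):
    """A random rotation matrix and translation vector."""
    from nadder.simulate import random_rotation
    return random_rotation(rng), rng.normal(scale=50.0, size=3)
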