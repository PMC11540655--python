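import numpy as np
import pytest

import brachysim as bs
from brachysim.constitutive import Material, MaterialField


@pytest.fixture(scope="session")
def default_phantom():
    """The default prostate-in-block phantom (80 mm block, 5 mm spacing)."""
    return bs.generate_phantom(bs.PhantomSpec())


@pytest.fixture(scope="session")
def default_shape_table(default_phantom):
    return bs.build_shape_table(default_phantom)


@pytest.fixture(scope="session")
def small_box():
    """Homogeneous 20 mm cube at 2 mm spacing for solver unit tests."""
    return bs.box_domain((20, 20, 20), 2.0)


@pytest.fixture(scope="session")
def small_box_table(small_box):
    return bs.build_shape_table(small_box)


@pytest.fixture(scope="session")
def prostate_material():
    return Material.from_young_poisson(25.0, 0.49)


@pytest.fixture(scope="session")
def small_box_field(small_box, prostate_material):
    return MaterialField.from_domain(small_box, {0: prostate_material,
                                                 1: prostate_material})


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_deformation_gradients(rng, n, det_lo=0.5, det_hi=2.0):
    """Random F with controlled determinant range."""
    out = []
    while len(out) < n:
        F = np.eye(3) + rng.normal(0, 0.25, (3, 3))
        d = np.linalg.det(F)
        if det_lo <= d <= det_hi:
            out.append(F)
    return np.array(out)


def random_rotations(rng, n):
    """Uniform-ish random rotation matrices via QR."""
    out = []
    for _ in range(n):
        q, r = np.linalg.qr(rng.normal(size=(3, 3)))
        q *= np.sign(np.diag(r))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        out.append(q)
    return np.array(out)
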