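import numpy as np
import pytest

from jointmorph.fe import Material
from jointmorph.meshing import REGION_CODE, REGIONS, tet_mesh_from_regions
from jointmorph.synthetic import ToyJointParams, generate_toy_joint_mesh


def cube_mesh(side=20.0, voxel=5.0, region="MC"):
    code = REGION_CODE[region]

    def region_of(pts):
        inside = ((pts >= 0) & (pts <= side)).all(axis=1)
        return np.where(inside, code, -1)

    return tet_mesh_from_regions(region_of, [[0] * 3, [side] * 3], voxel_size=voxel)


@pytest.fixture(scope="session")
def unit_cube():
    return cube_mesh()


@pytest.fixture(scope="session")
def uniform_materials():
    mat = Material(E=54.8, nu=0.3)
    return {name: mat for name in REGIONS}


@pytest.fixture(scope="session")
def toy_params():
    return ToyJointParams()


@pytest.fixture(scope="session")
def toy_mesh(toy_params):
    return generate_toy_joint_mesh(toy_params)


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
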