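import numpy as np
import pytest
import trimesh

from replica_accuracy import SurfaceMesh, make_phantom

COARSE_PITCH = 0.3  # mm; phantom resolution used by most unit tests


@pytest.fixture(scope="session")
def premolar():
    return make_phantom("premolar", seed=1, pitch=COARSE_PITCH)


@pytest.fixture(scope="session")
def canine():
    return make_phantom("canine", seed=1, pitch=COARSE_PITCH)


@pytest.fixture(scope="session")
def molar():
    return make_phantom("molar", seed=1, pitch=COARSE_PITCH)


@pytest.fixture(scope="session")
def phantoms(premolar, canine, molar):
    return {"premolar": premolar, "canine": canine, "molar": molar}


def icosphere(radius=1.0, subdivisions=3):
    return SurfaceMesh.from_trimesh(
        trimesh.creation.icosphere(subdivisions, radius=radius)
    )


@pytest.fixture(scope="session")
def sphere5():
    return icosphere(5.0, 4)


@pytest.fixture(scope="session")
def small_mesh_pairs():
    """Random small mesh pairs (<= 500 faces) for brute-force comparisons."""
    rng = np.random.default_rng(42)
    pairs = []
    for k in range(10):
        a = trimesh.creation.icosphere(2, radius=rng.uniform(0.5, 2.0))
        b = trimesh.creation.icosphere(2, radius=rng.uniform(0.5, 2.0))
        ta = np.eye(4)
        ta[:3, 3] = rng.uniform(-1, 1, 3)
        b.apply_transform(ta)
        b.apply_scale([1.0, rng.uniform(0.6, 1.4), rng.uniform(0.6, 1.4)])
        assert len(a.faces) <= 500 and len(b.faces) <= 500
        pairs.append((SurfaceMesh.from_trimesh(a), SurfaceMesh.from_trimesh(b)))
    return pairs
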