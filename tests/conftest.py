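import numpy as np
import pytest

from embolocate import synthetic_data as sd
from embolocate.ontology_assignment import AtlasOntology


@pytest.fixture(scope="session")
def hand_ontology() -> AtlasOntology:
    """Small hand-built tree with uneven branch depths.

    root(1)
      gray matter(2)
        cerebrum(4)
          cortex(6)   [leaf, level 4]
          nuclei(7)
            nucleus a(8)  [leaf, level 5]
            nucleus b(9)  [leaf, level 5]
        brainstem(5)  [leaf, level 3]
      fiber tracts(3) [leaf, level 2]
    """
    return AtlasOntology(
        [
            {"id": 1, "name": "root", "parent_structure_id": None},
            {"id": 2, "name": "gray matter", "parent_structure_id": 1},
            {"id": 3, "name": "fiber tracts", "parent_structure_id": 1},
            {"id": 4, "name": "cerebrum", "parent_structure_id": 2},
            {"id": 5, "name": "brainstem", "parent_structure_id": 2},
            {"id": 6, "name": "cortex", "parent_structure_id": 4},
            {"id": 7, "name": "nuclei", "parent_structure_id": 4},
            {"id": 8, "name": "nucleus a", "parent_structure_id": 7},
            {"id": 9, "name": "nucleus b", "parent_structure_id": 7},
        ]
    )


@pytest.fixture(scope="session")
def toy_atlas():
    """Seeded toy atlas: (ontology, annotation volume), 50-um voxels."""
    return sd.generate_toy_atlas(depth=5, branching=2, shape=(64, 64, 64), voxel_size_um=50.0, seed=7)


@pytest.fixture(scope="session")
def pipeline_atlas():
    """Toy atlas with voxel size equal to the section thickness (100 um)."""
    return sd.generate_toy_atlas(
        depth=7, branching=2, shape=(32, 32, 32), voxel_size_um=100.0, seed=11
    )


@pytest.fixture(scope="session")
def blob_image() -> np.ndarray:
    """A textured test image with a clear foreground for registration tests."""
    rng = np.random.default_rng(42)
    img = np.zeros((160, 160))
    yy, xx = np.mgrid[0:160, 0:160]
    for _ in range(25):
        cx, cy = rng.uniform(40, 120, size=2)
        s = rng.uniform(2, 6)
        a = rng.uniform(60, 255)
        img += a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * s**2))
    return np.clip(img, 0, 255).astype(np.uint8)
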