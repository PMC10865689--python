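import numpy as np
import pytest
import trimesh


@pytest.fixture(scope="session")
def icosphere_642():
    return trimesh.creation.icosphere(subdivisions=3)


@pytest.fixture(scope="session")
def icosphere_2562():
    return trimesh.creation.icosphere(subdivisions=4)


@pytest.fixture(scope="session")
def sphere_1000():
    from morphomcia.synthetic_cohort import fibonacci_sphere_mesh

    return fibonacci_sphere_mesh(1000)


@pytest.fixture(scope="session")
def small_cohort():
    """10 individuals x 3 organs at 300 vertices; meshes in correspondence."""
    from morphomcia.synthetic_cohort import CohortSpec, generate_cohort

    spec = CohortSpec(n_individuals=10, seed=11, n_vertices=300)
    meshes, truth = generate_cohort(spec)
    return spec, meshes, truth


@pytest.fixture(scope="session")
def standardized_blocks():
    """Three random standardized feature blocks over 12 individuals."""
    from morphomcia.shape_features import FeatureMatrix, standardize

    rng = np.random.default_rng(7)
    blocks = []
    for organ, d in (("a", 40), ("b", 25), ("c", 30)):
        fm = FeatureMatrix(
            X=rng.normal(size=(d, 12)),
            feature_names=[f"f{i}" for i in range(d)],
            organ=organ,
        )
        blocks.append(standardize(fm))
    return blocks
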