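import numpy as np
import pytest

from tmsmap.efield import FieldModel, build_candidate_set, generate_coil_grid
from tmsmap.geometry import ROIMesh, build_synthetic_roi, geodesic_distance_matrix


@pytest.fixture(scope="session")
def flat_mesh():
    return build_synthetic_roi(
        n_compartments=400, fold_amplitude=0.0, fold_wavelength=12.0,
        radius=20.0, seed=7,
    )


@pytest.fixture(scope="session")
def folded_mesh():
    return build_synthetic_roi(
        n_compartments=600, fold_amplitude=8.0, fold_wavelength=12.0,
        radius=20.0, seed=7,
    )


@pytest.fixture(scope="session")
def flat_gd(flat_mesh):
    return geodesic_distance_matrix(flat_mesh)


@pytest.fixture(scope="session")
def folded_gd(folded_mesh):
    return geodesic_distance_matrix(folded_mesh)


@pytest.fixture(scope="session")
def strip_mesh():
    """Four triangles in a row whose adjacency graph is a path."""
    vertices = np.array(
        [
            [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0],
            [0.5, 1.0, 0.0], [1.5, 1.0, 0.0], [2.5, 1.0, 0.0],
        ]
    )
    triangles = np.array([[0, 1, 3], [1, 4, 3], [1, 2, 4], [2, 5, 4]])
    centers = vertices[triangles].mean(axis=1)
    return ROIMesh(
        vertices=vertices, triangles=triangles, compartment_centers=centers,
        depth=np.zeros(4), roi_center=np.array([1.25, 0.5, 0.0]),
    )


@pytest.fixture(scope="session")
def small_candidates(flat_mesh):
    configs = generate_coil_grid(search_radius=15.0, spacing=7.5, angle_step=45.0)
    return build_candidate_set(flat_mesh, configs, FieldModel())


def scalar_candidates(values):
    """Matrix of 1-compartment candidate maps with the given |E| values."""
    return np.asarray(values, dtype=float)[:, None]
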