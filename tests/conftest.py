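"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from duramech.kinematics import deformation_history
from duramech.synthetic import (SphereInflationSpec, default_rig,
                                simulate_sphere_inflation)


@pytest.fixture(scope="session")
def sphere_spec():
    """Default study conditions with a short 6-frame schedule."""
    return SphereInflationSpec(stretch_schedule=np.linspace(1.0, 1.3, 6))


@pytest.fixture(scope="session")
def sphere_dataset(sphere_spec):
    return simulate_sphere_inflation(sphere_spec)


@pytest.fixture(scope="session")
def sphere_states(sphere_dataset, sphere_spec):
    return deformation_history(sphere_dataset,
                               h0=sphere_spec.initial_thickness)


@pytest.fixture(scope="session")
def rig():
    return default_rig()


@pytest.fixture()
def flat_mesh():
    """Regular flat triangulated square in the xy-plane, 6x6 nodes."""
    from scipy.spatial import Delaunay

    g = np.linspace(0.0, 1.0, 6)
    xx, yy = np.meshgrid(g, g, indexing="ij")
    pts2 = np.column_stack([xx.ravel(), yy.ravel()])
    tri = Delaunay(pts2)
    nodes = np.column_stack([pts2, np.zeros(len(pts2))])
    from duramech.mesh import TriMesh

    return TriMesh(nodes, tri.simplices, thickness=375e-6)
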