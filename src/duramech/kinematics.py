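"""Per-element membrane kinematics: deformation gradient, log strain, thickness.

Each triangular element carries an orthonormal in-plane reference frame
{U, V}, with U the in-plane projection of a chosen global direction (e.g. the
medio-lateral axis) and V its complement.  The element's affine map is solved
from the three nodal position pairs; the reference frame is carried into the
deformed element plane by the minimal rotation aligning the element normals,
and the 2x2 in-plane deformation gradient F collects the components of the
advected frame vectors in the carried basis.  This reproduces any homogeneous
in-plane map exactly and is objective: a superposed rigid motion leaves the
strain measures unchanged.

From F follow the logarithmic strain E = 1/2 log(F^T F) (by eigendecomposition
of the right Cauchy-Green tensor), the principal stretches, and the
incompressible current thickness h = h0 / det F.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TriMesh

__all__ = [
    "LocalFrame",
    "DeformationState",
    "element_bases",
    "element_deformation",
    "update_thickness",
    "deformation_history",
]


@dataclass
class LocalFrame:
    """Orthonormal in-plane reference vectors per element."""

    U: np.ndarray  # (m, 3)
    V: np.ndarray  # (m, 3)


@dataclass
class DeformationState:
    """Per-element kinematic state of one frame."""

    F: np.ndarray        # (m, 2, 2) in-plane deformation gradient
    E: np.ndarray        # (m, 2, 2) logarithmic strain
    lambda1: np.ndarray  # (m,) larger principal stretch
    lambda2: np.ndarray  # (m,) smaller principal stretch
    h0: np.ndarray       # (m,) reference thickness (m)
    h: np.ndarray        # (m,) current thickness (m)
    volume: np.ndarray   # (m,) reference element volume (m^3)


def element_bases(mesh: TriMesh, global_direction) -> LocalFrame:
    """In-plane frame per element from the projection of a global direction.

    ``U`` is the normalised in-plane projection of ``global_direction`` and
    ``V = normal x U``.  Elements whose normal is (numerically) parallel to
    the direction have no well-defined projection and raise.
    """
    d = np.asarray(global_direction, float)
    d = d / np.linalg.norm(d)
    normals, _ = mesh.element_normals_areas()
    proj = d[None, :] - (normals @ d)[:, None] * normals
    nrm = np.linalg.norm(proj, axis=1)
    bad = np.flatnonzero(nrm < 1e-6)
    if bad.size:
        raise ValueError(
            f"global direction parallel to normals of elements {bad.tolist()}")
    U = proj / nrm[:, None]
    V = np.cross(normals, U)
    return LocalFrame(U=U, V=V)


def _minimal_rotations(n0: np.ndarray, n1: np.ndarray) -> np.ndarray:
    """(m, 3, 3) smallest rotations carrying unit vectors n0 onto n1."""
    c = np.einsum("ij,ij->i", n0, n1)
    if np.any(c < -0.999999):
        bad = np.flatnonzero(c < -0.999999).tolist()
        raise ValueError(f"elements flipped through the plane: {bad}")
    v = np.cross(n0, n1)
    m = len(n0)
    K = np.zeros((m, 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -v[:, 2], v[:, 1]
    K[:, 1, 0], K[:, 1, 2] = v[:, 2], -v[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -v[:, 1], v[:, 0]
    # Rodrigues with sin = |v|, cos = c: R = I + K + K^2 / (1 + c)
    return (np.eye(3)[None] + K
            + np.einsum("mij,mjk->mik", K, K) / (1.0 + c)[:, None, None])


def element_deformation(ref_mesh: TriMesh, def_positions: np.ndarray,
                        frames: LocalFrame,
                        h0: np.ndarray | float | None = None
                        ) -> DeformationState:
    """Deformation state of every element for one deformed configuration.

    ``h0`` may be a scalar, a per-element array, or ``None`` to use the
    mesh's own thickness field.
    """
    def_positions = np.asarray(def_positions, float)
    if def_positions.shape != ref_mesh.nodes.shape:
        raise ValueError("deformed positions must match the reference mesh")
    if h0 is None:
        if ref_mesh.thickness is None:
            raise ValueError("no thickness supplied and mesh has none")
        h0_e = ref_mesh.thickness
    else:
        h0_e = np.broadcast_to(np.asarray(h0, float),
                               (ref_mesh.n_elements,)).copy()

    tri_ref = ref_mesh.element_nodes()
    tri_def = ref_mesh.element_nodes(def_positions)
    D1, D2 = tri_ref[:, 1] - tri_ref[:, 0], tri_ref[:, 2] - tri_ref[:, 0]
    d1, d2 = tri_def[:, 1] - tri_def[:, 0], tri_def[:, 2] - tri_def[:, 0]

    n_ref, area_ref = ref_mesh.element_normals_areas()
    cross_def = np.cross(d1, d2)
    nrm_def = np.linalg.norm(cross_def, axis=1)
    if np.any(nrm_def <= 0):
        bad = np.flatnonzero(nrm_def <= 0).tolist()
        raise ValueError(f"folded (zero-area) deformed elements: {bad}")
    n_def = cross_def / nrm_def[:, None]

    U, V = frames.U, frames.V
    # reference edge coordinates in the {U, V} frame
    M = np.stack([
        np.stack([np.einsum("ij,ij->i", D1, U),
                  np.einsum("ij,ij->i", D2, U)], axis=-1),
        np.stack([np.einsum("ij,ij->i", D1, V),
                  np.einsum("ij,ij->i", D2, V)], axis=-1),
    ], axis=1)                                           # (m, 2, 2)
    Minv = np.linalg.inv(M)
    # advected frame vectors: U = a D1 + b D2  ->  u = a d1 + b d2
    cu = Minv[:, :, 0]   # coefficients of U in the edge basis
    cv = Minv[:, :, 1]
    u = cu[:, 0:1] * d1 + cu[:, 1:2] * d2
    v = cv[:, 0:1] * d1 + cv[:, 1:2] * d2

    Q = _minimal_rotations(n_ref, n_def)
    Uc = np.einsum("mij,mj->mi", Q, U)   # carried basis in the deformed plane
    Vc = np.einsum("mij,mj->mi", Q, V)

    F = np.empty((ref_mesh.n_elements, 2, 2))
    F[:, 0, 0] = np.einsum("ij,ij->i", u, Uc)
    F[:, 0, 1] = np.einsum("ij,ij->i", v, Uc)
    F[:, 1, 0] = np.einsum("ij,ij->i", u, Vc)
    F[:, 1, 1] = np.einsum("ij,ij->i", v, Vc)

    detF = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
    if np.any(detF <= 0):
        bad = np.flatnonzero(detF <= 0).tolist()
        raise ValueError(f"non-positive det F (folded elements): {bad}")

    C = np.einsum("mji,mjk->mik", F, F)  # F^T F, symmetric positive definite
    evals, evecs = np.linalg.eigh(C)
    if np.any(evals <= 0):
        bad = np.flatnonzero((evals <= 0).any(axis=1)).tolist()
        raise ValueError(f"non-positive-definite F^T F at elements: {bad}")
    logC = np.einsum("mik,mk,mjk->mij", evecs, np.log(evals), evecs)
    E = 0.5 * logC
    lam = np.sqrt(evals)
    lambda1, lambda2 = lam[:, 1], lam[:, 0]   # eigh sorts ascending

    h = update_thickness(h0_e, F)
    return DeformationState(F=F, E=E, lambda1=lambda1, lambda2=lambda2,
                            h0=h0_e, h=h, volume=area_ref * h0_e)


def update_thickness(h0, F: np.ndarray):
    """Incompressible thickness update ``h = h0 / det F``."""
    F = np.asarray(F, float)
    detF = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    if np.any(detF <= 0):
        raise ValueError("det F must be positive")
    return np.asarray(h0, float) / detF


def deformation_history(dataset, global_direction=(1.0, 0.0, 0.0),
                        h0=None) -> list[DeformationState]:
    """Deformation states of every frame of an inflation dataset."""
    bases = element_bases(dataset.mesh, global_direction)
    return [element_deformation(dataset.mesh, dataset.frames[k], bases, h0)
            for k in range(dataset.n_frames)]
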