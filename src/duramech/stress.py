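"""Inverse membrane equilibrium: local Cauchy stress from pressure and shape.

Under a pure membrane assumption (no bending stiffness, zero through-thickness
stress) the in-plane Cauchy stress field of a pressurized membrane is
statically determinate up to discretization: writing force equilibrium of
every deformed triangular element,

    p A_e n_e + sum_edges h_e L (sigma_edge . m_edge) = 0,

with sigma_edge the mean of the two end-node stress tensors, m_edge the
outward in-plane edge normal and h_e the current thickness, gives three
scalar equations per element in the 3 x n_nodes unknown nodal components
(sigma_uu, sigma_vv, sigma_uv in nodal tangent bases).  Rim rows require the
clamped-edge traction to have no shear (component along the edge) and no
moment (component along the surface normal; identically satisfied by the
in-plane parameterization, assembled anyway for completeness).  The
overdetermined system is solved in the least-squares sense with column
scaling, and the nodal tensors are then distributed over the elements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import lstsq as _dense_lstsq
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import lsmr as _lsmr

from .mesh import TriMesh

__all__ = [
    "StressField",
    "RuptureRecord",
    "assemble_equilibrium",
    "lstsq_nodal_stress",
    "solve_membrane_stress",
    "principal_ratio_map",
    "rupture_stress",
]


@dataclass
class StressField:
    """In-plane Cauchy stress field of one frame."""

    node_components: np.ndarray  # (n, 3): sigma_uu, sigma_vv, sigma_uv (Pa)
    node_U: np.ndarray           # (n, 3) nodal tangent basis
    node_V: np.ndarray
    element_tensor: np.ndarray   # (m, 2, 2) in element bases (Pa)
    sigma1: np.ndarray           # (m,) first principal Cauchy stress
    sigma2: np.ndarray           # (m,)
    element_area: np.ndarray     # (m,) deformed areas (m^2)
    residual: float              # ||A x - b|| / ||b||


@dataclass
class RuptureRecord:
    """Local failure stress extracted just before the burst frame."""

    rupture_frame: int
    mask: np.ndarray             # element indices of the damaged area
    failure_stress: float        # area-weighted mean sigma1 (Pa)


def _nodal_tangent_bases(mesh: TriMesh, positions: np.ndarray):
    """Orthonormal tangent pair per node from averaged adjacent normals."""
    n = mesh.node_normals(positions)
    # seed direction: global axis least aligned with the mean normal
    seed = np.eye(3)[np.argmin(np.abs(n.mean(axis=0)))]
    proj = seed[None] - (n @ seed)[:, None] * n
    nrm = np.linalg.norm(proj, axis=1)
    # fall back to another axis where the seed is parallel to the normal
    weak = nrm < 1e-6
    if np.any(weak):
        alt = np.roll(seed, 1)
        proj[weak] = alt[None] - (n[weak] @ alt)[:, None] * n[weak]
        nrm[weak] = np.linalg.norm(proj[weak], axis=1)
    U = proj / nrm[:, None]
    V = np.cross(n, U)
    return U, V, n


def _basis_tensors(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """(n, 3, 3, 3) symmetric basis tensors for (s_uu, s_vv, s_uv)."""
    B = np.empty((len(U), 3, 3, 3))
    B[:, 0] = np.einsum("ni,nj->nij", U, U)
    B[:, 1] = np.einsum("ni,nj->nij", V, V)
    B[:, 2] = (np.einsum("ni,nj->nij", U, V)
               + np.einsum("ni,nj->nij", V, U))
    return B


def assemble_equilibrium(mesh: TriMesh, positions: np.ndarray,
                         pressure: float, thickness: np.ndarray | float):
    """Assemble the element-equilibrium least-squares system ``A x = b``.

    Rows are the three force-balance components per element followed by the
    no-shear / no-moment rows per boundary node; unknowns are the three
    in-plane stress components per node in the nodal tangent bases.  Returns
    ``(A, b, (U, V, node_normals))`` with A in CSR form.
    """
    positions = np.asarray(positions, float)
    if pressure < 0:
        raise ValueError("pressure must be >= 0")
    h_e = np.broadcast_to(np.asarray(thickness, float),
                          (mesh.n_elements,)).copy()
    if np.any(h_e <= 0):
        raise ValueError("thickness must be positive")

    tris = mesh.triangles
    n_nodes, n_elem = mesh.n_nodes, mesh.n_elements
    normals, areas = mesh.element_normals_areas(positions)
    U, V, node_n = _nodal_tangent_bases(mesh, positions)
    B = _basis_tensors(U, V)     # (n_nodes, 3, 3, 3)

    rows, cols, vals = [], [], []
    b = np.zeros(3 * n_elem)

    # average facet normal per undirected edge: the traction transmitted
    # across a shared edge must be equal and opposite for its two elements
    # (action-reaction), so both sides evaluate it in the same edge plane
    edge_normal_sum: dict[tuple[int, int], np.ndarray] = {}
    edge_h_sum: dict[tuple[int, int], list] = {}
    for e in range(n_elem):
        for a, bb in ((0, 1), (1, 2), (2, 0)):
            key = tuple(sorted((int(tris[e, a]), int(tris[e, bb]))))
            edge_normal_sum[key] = edge_normal_sum.get(key, 0.0) + normals[e]
            edge_h_sum.setdefault(key, []).append(h_e[e])
    edge_normal = {k: v / np.linalg.norm(v)
                   for k, v in edge_normal_sum.items()}
    edge_h = {k: float(np.mean(v)) for k, v in edge_h_sum.items()}

    # each element's force balance is normalized by its thickness so the
    # equations stay balanced against the (thickness-free) edge rows and the
    # solution scales exactly inversely with a uniform thickness change
    for e in range(n_elem):
        i0 = 3 * e
        b[i0:i0 + 3] = -pressure * areas[e] * normals[e] / h_e[e]
        for a, bb in ((0, 1), (1, 2), (2, 0)):
            na, nb = int(tris[e, a]), int(tris[e, bb])
            key = (na, nb) if na < nb else (nb, na)
            edge = positions[nb] - positions[na]
            L = np.linalg.norm(edge)
            m_out = np.cross(edge / L, edge_normal[key])
            m_out /= np.linalg.norm(m_out)
            scale = 0.5 * L * edge_h[key] / h_e[e]
            for node in (na, nb):
                # traction contribution: 0.5 L h_edge / h_e (B_c . m) rows
                contrib = scale * (B[node] @ m_out)     # (3 comp, 3D)
                for c in range(3):
                    for d in range(3):
                        rows.append(i0 + d)
                        cols.append(3 * node + c)
                        vals.append(contrib[c, d])

    # clamped-rim rows: no shear (along edge) and no moment (along normal)
    bedges = mesh.boundary_edges()
    bnode_rows = []
    if len(bedges):
        neigh: dict[int, list[int]] = {}
        for a, bb in bedges:
            neigh.setdefault(int(a), []).append(int(bb))
            neigh.setdefault(int(bb), []).append(int(a))
        row0 = 3 * n_elem
        r = row0
        for v, nbrs in sorted(neigh.items()):
            if len(nbrs) == 2:
                e_dir = positions[nbrs[1]] - positions[nbrs[0]]
            else:
                e_dir = positions[nbrs[0]] - positions[v]
            e_dir = e_dir / np.linalg.norm(e_dir)
            # in-plane projection, orthogonal to the nodal normal
            e_dir = e_dir - (e_dir @ node_n[v]) * node_n[v]
            e_dir /= np.linalg.norm(e_dir)
            m_dir = np.cross(e_dir, node_n[v])
            tract = B[v] @ m_dir        # (3 components, 3D traction)
            for probe in (e_dir, node_n[v]):   # no shear; no moment
                for c in range(3):
                    rows.append(r)
                    cols.append(3 * v + c)
                    vals.append(tract[c] @ probe)
                r += 1
            bnode_rows.append(v)
        n_rows = r
    else:
        n_rows = 3 * n_elem
    b = np.concatenate([b, np.zeros(n_rows - 3 * n_elem)])

    A = coo_matrix((vals, (rows, cols)), shape=(n_rows, 3 * n_nodes)).tocsr()
    return A, b, (U, V, node_n)


def lstsq_nodal_stress(A, b) -> tuple[np.ndarray, float]:
    """Column-scaled least-squares solve; returns (x, relative residual)."""
    n_unknowns = A.shape[1]
    col_scale = np.sqrt(np.asarray(A.multiply(A).sum(axis=0)).ravel())
    col_scale[col_scale == 0] = 1.0
    As = A.multiply(1.0 / col_scale[None, :]).tocsr()

    if n_unknowns <= 6000:
        x_s, _, rank, _ = _dense_lstsq(As.toarray(), b,
                                       lapack_driver="gelsy")
        if rank < n_unknowns:
            raise ValueError(
                f"rank-deficient equilibrium system: null-space dimension "
                f"{n_unknowns - rank}")
    else:
        x_s = _lsmr(As, b, atol=1e-12, btol=1e-12, maxiter=20000)[0]
    x = x_s / col_scale

    resid_vec = A @ x - b
    bnorm = np.linalg.norm(b)
    residual = float(np.linalg.norm(resid_vec) / bnorm) if bnorm > 0 else 0.0
    return x, residual


def solve_membrane_stress(mesh: TriMesh, positions: np.ndarray,
                          pressure: float,
                          thickness: np.ndarray | float,
                          element_frames=None) -> StressField:
    """Least-squares nodal Cauchy stresses of one deformed frame.

    Parameters
    ----------
    mesh : TriMesh
        Topology (and reference geometry, unused here).
    positions : (n_nodes, 3)
        Deformed nodal positions; triangles must wind counter-clockwise seen
        from the pressurized (outward-normal) side.
    pressure : float
        Chamber gauge pressure (Pa), >= 0.
    thickness : float or (n_elements,)
        Current (deformed) thickness per element (m).
    element_frames : LocalFrame, optional
        Element bases in which the element tensors are expressed; defaults to
        the projection of the same seed direction used for the nodal bases.
    """
    positions = np.asarray(positions, float)
    tris = mesh.triangles
    n_nodes, n_elem = mesh.n_nodes, mesh.n_elements
    normals, areas = mesh.element_normals_areas(positions)

    A, b, (U, V, node_n) = assemble_equilibrium(mesh, positions, pressure,
                                                thickness)
    B = _basis_tensors(U, V)
    x, residual = lstsq_nodal_stress(A, b)

    node_components = x.reshape(n_nodes, 3)
    sigma_nodes = np.einsum("nc,ncij->nij", node_components, B)  # 3D tensors

    if element_frames is None:
        from .kinematics import element_bases

        seed = np.eye(3)[np.argmin(np.abs(normals.mean(axis=0)))]
        dmesh = TriMesh(positions, tris)
        element_frames = element_bases(dmesh, seed)
    Ue, Ve = element_frames.U, element_frames.V

    elem_tensor = np.zeros((n_elem, 2, 2))
    for k in range(3):
        s = sigma_nodes[tris[:, k]]
        suu = np.einsum("mi,mij,mj->m", Ue, s, Ue)
        svv = np.einsum("mi,mij,mj->m", Ve, s, Ve)
        suv = 0.5 * (np.einsum("mi,mij,mj->m", Ue, s, Ve)
                     + np.einsum("mi,mij,mj->m", Ve, s, Ue))
        elem_tensor[:, 0, 0] += suu
        elem_tensor[:, 1, 1] += svv
        elem_tensor[:, 0, 1] += suv
        elem_tensor[:, 1, 0] += suv
    elem_tensor /= 3.0

    evals = np.linalg.eigvalsh(elem_tensor)
    sigma1, sigma2 = evals[:, 1], evals[:, 0]

    return StressField(node_components=node_components, node_U=U, node_V=V,
                       element_tensor=elem_tensor, sigma1=sigma1,
                       sigma2=sigma2, element_area=areas, residual=residual)


def principal_ratio_map(first: np.ndarray, second: np.ndarray,
                        tol: float = 1e-12) -> np.ndarray:
    """Per-element ratio of first to second principal value.

    Elements whose second principal value is smaller than ``tol`` in
    magnitude are masked with NaN.
    """
    first = np.asarray(first, float)
    second = np.asarray(second, float)
    out = np.full_like(first, np.nan)
    ok = np.abs(second) >= tol
    out[ok] = first[ok] / second[ok]
    return out


def rupture_stress(stress_frames: list[StressField], mask,
                   rupture_frame: int,
                   mesh: TriMesh | None = None) -> RuptureRecord:
    """Area-weighted mean first-principal stress just before rupture.

    ``mask`` lists the element indices of the damaged area selected on the
    first frame showing visible damage (``rupture_frame``); the stress is
    taken from the preceding frame.
    """
    mask = np.asarray(mask, dtype=np.intp)
    if mask.size == 0:
        raise ValueError("damage mask is empty")
    if rupture_frame < 1:
        raise ValueError("rupture_frame must be >= 1 (needs a preceding frame)")
    if rupture_frame >= len(stress_frames):
        raise ValueError("rupture_frame beyond available stress frames")
    if mesh is not None:
        rim = set(mesh.boundary_nodes().tolist())
        if any(rim.intersection(mesh.triangles[e]) for e in mask):
            warnings.warn(
                "damage mask touches the clamped boundary; local failure "
                "stress there is unreliable", stacklevel=2)
    field = stress_frames[rupture_frame - 1]
    w = field.element_area[mask]
    value = float(np.average(field.sigma1[mask], weights=w))
    return RuptureRecord(rupture_frame=int(rupture_frame), mask=mask,
                         failure_stress=value)
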