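"""Triangulated-membrane container and geometric helpers.

A :class:`TriMesh` is the geometric substrate shared by every stage of the
inflation pipeline: the synthetic generator emits one, the stereo module
reconstructs one from feature tracks, and the kinematics/stress modules
consume the reference mesh together with per-frame deformed nodal positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TriMesh", "InflationDataset"]


@dataclass
class TriMesh:
    """Triangulated surface with optional per-element reference thickness.

    Parameters
    ----------
    nodes : (n_nodes, 3) float array
        Node positions in metres, world frame (right-handed).
    triangles : (n_elements, 3) int array
        Node indices, counter-clockwise when viewed from the outward side.
    thickness : float or (n_elements,) array, optional
        Reference thickness h0 per element (m). A scalar is broadcast.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    thickness: np.ndarray | float | None = None

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.intp)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        if self.thickness is not None:
            self.thickness = np.broadcast_to(
                np.asarray(self.thickness, dtype=float), (self.n_elements,)
            ).copy()

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    def element_nodes(self, positions: np.ndarray | None = None) -> np.ndarray:
        """(m, 3, 3) array of the three node positions of every element."""
        pos = self.nodes if positions is None else np.asarray(positions, float)
        return pos[self.triangles]

    def element_normals_areas(
        self, positions: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Unit normals (m, 3) and areas (m,) of every element."""
        tri = self.element_nodes(positions)
        cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        nrm = np.linalg.norm(cross, axis=1)
        if np.any(nrm <= 0):
            bad = np.flatnonzero(nrm <= 0)
            raise ValueError(f"degenerate (zero-area) elements: {bad.tolist()}")
        return cross / nrm[:, None], 0.5 * nrm

    def node_normals(self, positions: np.ndarray | None = None) -> np.ndarray:
        """Area-weighted average of adjacent element normals, unit length."""
        normals, areas = self.element_normals_areas(positions)
        acc = np.zeros((self.n_nodes, 3))
        weighted = normals * areas[:, None]
        for k in range(3):
            np.add.at(acc, self.triangles[:, k], weighted)
        nrm = np.linalg.norm(acc, axis=1)
        nrm[nrm == 0] = 1.0
        return acc / nrm[:, None]

    def boundary_edges(self) -> np.ndarray:
        """(k, 2) node-index pairs of edges used by exactly one element."""
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]],
             self.triangles[:, [2, 0]]]
        )
        key = np.sort(e, axis=1)
        _, idx, counts = np.unique(key, axis=0, return_index=True,
                                   return_counts=True)
        return e[idx[counts == 1]]

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_edges())

    def interior_elements(self, rings: int = 2) -> np.ndarray:
        """Element indices whose nodes are all >= `rings` edge-hops from the rim.

        Used to restrict oracle comparisons to the region where a uniform
        forward model satisfies equilibrium (away from the clamped edge).
        """
        far = np.ones(self.n_nodes, dtype=bool)
        frontier = np.zeros(self.n_nodes, dtype=bool)
        frontier[self.boundary_nodes()] = True
        adj = _node_adjacency(self.triangles, self.n_nodes)
        for _ in range(rings):
            far &= ~frontier
            nxt = np.zeros_like(frontier)
            for v in np.flatnonzero(frontier):
                nxt[adj[v]] = True
            frontier |= nxt
        far &= ~frontier
        return np.flatnonzero(far[self.triangles].all(axis=1))


def _node_adjacency(triangles: np.ndarray, n_nodes: int) -> list[np.ndarray]:
    nbr: list[set[int]] = [set() for _ in range(n_nodes)]
    for a, b, c in triangles:
        nbr[a].update((b, c))
        nbr[b].update((a, c))
        nbr[c].update((a, b))
    return [np.fromiter(s, dtype=np.intp) for s in nbr]


@dataclass
class InflationDataset:
    """Ordered inflation frames over a common reference mesh.

    Attributes
    ----------
    mesh : TriMesh
        Reference (frame 0) geometry with per-element h0.
    frames : (n_frames, n_nodes, 3) array
        Deformed nodal positions per frame; frame 0 equals the reference.
    pressures : (n_frames,) array
        Chamber gauge pressure per frame (Pa).
    times : (n_frames,) array, optional
    ground_truth : dict, optional
        Per-frame per-element truth from the generator (F, stretches,
        thickness, stress); absent for experimental data.
    """

    mesh: TriMesh
    frames: np.ndarray
    pressures: np.ndarray
    times: np.ndarray | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.frames.shape[0] != self.pressures.shape[0]:
            raise ValueError("frames and pressures length mismatch")
        if self.frames.shape[1:] != (self.mesh.n_nodes, 3):
            raise ValueError("frame shape does not match mesh")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]
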