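"""Stereo surface reconstruction and sparse-track processing.

The deformed membrane surface is measured by two calibrated pinhole cameras.
This module turns pixel correspondences into 3D points (linear DLT plus one
Gauss-Newton refinement), filters sparse feature tracks (full-length rule and
a robust mean-velocity outlier rule), interpolates scattered surface data with
robust locally weighted quadratic regression (LOWESS), and assembles the
analysis mesh with per-frame nodal positions.

Feature detection inside images is out of scope: the pipeline consumes
trajectories (pixel coordinates per track, frame and camera).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, cKDTree

from .mesh import TriMesh

__all__ = [
    "CameraModel",
    "FeatureTrack",
    "MeshSpec",
    "DegenerateGeometryError",
    "triangulate_points",
    "filter_tracks",
    "lowess_surface",
    "build_frames",
    "tracks_from_dataframe",
]

MIN_TRIANGULATION_ANGLE_DEG = 0.1


class DegenerateGeometryError(RuntimeError):
    """Raised when viewing rays are too close to parallel to intersect."""


@dataclass
class CameraModel:
    """Pinhole camera: ``pixel ~ K (R X + t)``.

    K is upper triangular with positive focal entries; R is a proper rotation.
    Pixel origin is at the top-left corner, x right, y down; world units are
    metres.
    """

    K: np.ndarray
    R: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, float)
        self.R = np.asarray(self.R, float)
        self.t = np.asarray(self.t, float).reshape(3)
        if self.K.shape != (3, 3) or self.R.shape != (3, 3):
            raise ValueError("K and R must be 3x3")
        if not np.allclose(self.K, np.triu(self.K)):
            raise ValueError("intrinsic matrix must be upper triangular")
        if self.K[0, 0] <= 0 or self.K[1, 1] <= 0:
            raise ValueError("focal entries must be positive")
        if not np.allclose(self.R @ self.R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.R) < 0:
            raise ValueError("rotation must have det +1")

    @property
    def P(self) -> np.ndarray:
        """3x4 projection matrix K [R | t]."""
        return self.K @ np.hstack([self.R, self.t[:, None]])

    @property
    def center(self) -> np.ndarray:
        """Camera centre in world coordinates."""
        return -self.R.T @ self.t

    def project(self, X: np.ndarray) -> np.ndarray:
        """Project world points (n, 3) to pixel coordinates (n, 2)."""
        X = np.atleast_2d(np.asarray(X, float))
        cam = X @ self.R.T + self.t
        if np.any(cam[:, 2] <= 0):
            raise ValueError("points behind the camera")
        uvw = cam @ self.K.T
        return uvw[:, :2] / uvw[:, 2:3]

    def to_dict(self) -> dict:
        return {"K": self.K.tolist(), "R": self.R.tolist(),
                "t": self.t.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(np.array(d["K"]), np.array(d["R"]), np.array(d["t"]))


@dataclass
class FeatureTrack:
    """One tracked speckle feature: pixel positions per frame and camera."""

    track_id: int
    left: np.ndarray    # (n_frames, 2)
    right: np.ndarray   # (n_frames, 2)
    valid: np.ndarray   # (n_frames,) bool

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, float)
        self.right = np.asarray(self.right, float)
        self.valid = np.asarray(self.valid, bool)
        if not (len(self.left) == len(self.right) == len(self.valid)):
            raise ValueError("per-frame arrays must have equal length")
        ok = self.valid
        if not (np.isfinite(self.left[ok]).all()
                and np.isfinite(self.right[ok]).all()):
            raise ValueError("coordinates must be finite where valid")

    @property
    def n_frames(self) -> int:
        return len(self.valid)

    @property
    def full_length(self) -> bool:
        return bool(self.valid.all())

    def mean_speed(self) -> float:
        """Mean per-frame pixel displacement, averaged over both cameras."""
        dl = np.linalg.norm(np.diff(self.left, axis=0), axis=1)
        dr = np.linalg.norm(np.diff(self.right, axis=0), axis=1)
        return float(np.mean(0.5 * (dl + dr)))


def tracks_from_dataframe(df: pd.DataFrame,
                          n_frames: int | None = None) -> list[FeatureTrack]:
    """Build :class:`FeatureTrack` objects from a long-format tracks table."""
    if n_frames is None:
        n_frames = int(df["frame"].max()) + 1
    tracks = []
    for tid, grp in df.groupby("track_id"):
        left = np.full((n_frames, 2), np.nan)
        right = np.full((n_frames, 2), np.nan)
        for cam, arr in (("L", left), ("R", right)):
            sub = grp[grp["cam"] == cam]
            arr[sub["frame"].to_numpy(int)] = sub[["u_px", "v_px"]].to_numpy()
        valid = np.isfinite(left).all(axis=1) & np.isfinite(right).all(axis=1)
        left[~valid] = 0.0
        right[~valid] = 0.0
        tracks.append(FeatureTrack(int(tid), left, right, valid))
    return tracks


# ---------------------------------------------------------------------------
# Triangulation
# ---------------------------------------------------------------------------

def triangulate_points(correspondences_left: np.ndarray,
                       correspondences_right: np.ndarray,
                       cam_left: CameraModel,
                       cam_right: CameraModel) -> np.ndarray:
    """Triangulate paired pixel correspondences into 3D points.

    Each point is the linear-DLT solution refined by one Gauss-Newton step on
    the four reprojection residuals, i.e. a least-squares intersection of the
    two viewing rays in image space.

    Raises
    ------
    DegenerateGeometryError
        If the two viewing rays of any correspondence subtend less than
        0.1 degrees (near-parallel rays; the 3D point is unconstrained).
    """
    uvL = np.atleast_2d(np.asarray(correspondences_left, float))
    uvR = np.atleast_2d(np.asarray(correspondences_right, float))
    if uvL.shape != uvR.shape or uvL.shape[0] < 1:
        raise ValueError("correspondence arrays must be equal-shaped, >= 1 row")
    PL, PR = cam_left.P, cam_right.P
    CL, CR = cam_left.center, cam_right.center
    pts = np.empty((len(uvL), 3))
    min_cos = np.cos(np.deg2rad(MIN_TRIANGULATION_ANGLE_DEG))
    degenerate = []
    for i, ((uL, vL), (uR, vR)) in enumerate(zip(uvL, uvR)):
        A = np.vstack([
            uL * PL[2] - PL[0],
            vL * PL[2] - PL[1],
            uR * PR[2] - PR[0],
            vR * PR[2] - PR[1],
        ])
        _, _, Vt = np.linalg.svd(A)
        Xh = Vt[-1]
        if abs(Xh[3]) < 1e-12 * np.linalg.norm(Xh[:3]):
            degenerate.append(i)
            pts[i] = np.nan
            continue
        X = Xh[:3] / Xh[3]
        d1 = X - CL
        d2 = X - CR
        cosang = abs(d1 @ d2) / (np.linalg.norm(d1) * np.linalg.norm(d2))
        if cosang > min_cos:
            degenerate.append(i)
            pts[i] = np.nan
            continue
        pts[i] = _refine_point(X, (uL, vL), (uR, vR), cam_left, cam_right)
    if degenerate:
        raise DegenerateGeometryError(
            f"near-parallel viewing rays for correspondences {degenerate}")
    return pts


def _refine_point(X, uvL, uvR, camL, camR):
    """One Gauss-Newton step on the stacked reprojection residual."""
    r, J = _reproj_residual(X, uvL, uvR, camL, camR)
    try:
        dX = np.linalg.solve(J.T @ J, J.T @ r)
    except np.linalg.LinAlgError:
        return X
    return X - dX


def _reproj_residual(X, uvL, uvR, camL, camR):
    res = np.empty(4)
    J = np.empty((4, 3))
    for k, (cam, uv) in enumerate(((camL, uvL), (camR, uvR))):
        x = cam.R @ X + cam.t
        K = cam.K
        u = (K[0, 0] * x[0] + K[0, 1] * x[1] + K[0, 2] * x[2]) / x[2]
        v = (K[1, 1] * x[1] + K[1, 2] * x[2]) / x[2]
        res[2 * k] = u - uv[0]
        res[2 * k + 1] = v - uv[1]
        # d(u)/dX = d(u)/dx . R
        du = np.array([K[0, 0] / x[2], K[0, 1] / x[2],
                       -(K[0, 0] * x[0] + K[0, 1] * x[1]) / x[2] ** 2])
        dv = np.array([0.0, K[1, 1] / x[2], -K[1, 1] * x[1] / x[2] ** 2])
        J[2 * k] = du @ cam.R
        J[2 * k + 1] = dv @ cam.R
    return res, J


# ---------------------------------------------------------------------------
# Track filtering
# ---------------------------------------------------------------------------

def filter_tracks(tracks: list[FeatureTrack], n_frames: int,
                  k_mad: float = 5.0) -> list[FeatureTrack]:
    """Keep full-length tracks, then drop mean-velocity outliers.

    A track survives if (a) it is valid in all ``n_frames`` frames and (b) its
    mean pixel speed lies within ``k_mad`` median-absolute-deviations of the
    population median speed.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    full = [t for t in tracks
            if t.n_frames >= n_frames and t.valid[:n_frames].all()]
    if not full:
        raise ValueError("no track spans all frames")
    speeds = np.array([t.mean_speed() for t in full])
    med = np.median(speeds)
    mad = np.median(np.abs(speeds - med))
    kept = [t for t, s in zip(full, speeds) if abs(s - med) <= k_mad * mad]
    if not kept:
        raise ValueError("all tracks rejected by the mean-velocity filter")
    return kept


# ---------------------------------------------------------------------------
# Robust quadratic LOWESS
# ---------------------------------------------------------------------------

def lowess_surface(sample_xy: np.ndarray, values: np.ndarray,
                   query_xy: np.ndarray, span: float = 0.15,
                   robust_iter: int = 4) -> np.ndarray:
    """Locally weighted quadratic regression with bisquare robustness.

    At each query location a quadratic polynomial in the two in-plane
    coordinates is fitted to the ``span`` fraction of nearest samples with
    tricube distance weights; gross outliers are suppressed by
    ``robust_iter`` iterations of bisquare reweighting of the residuals at
    the sample locations. Vector-valued fields are interpolated
    componentwise.

    Returns the fitted values at ``query_xy`` with the same trailing shape
    as ``values``.
    """
    sample_xy = np.asarray(sample_xy, float)
    query_xy = np.atleast_2d(np.asarray(query_xy, float))
    values = np.asarray(values, float)
    squeeze = values.ndim == 1
    vals = values[:, None] if squeeze else values
    n = len(sample_xy)
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    k = max(8, int(np.ceil(span * n)))
    k = min(k, n)
    if n < 6:
        raise ValueError("need at least 6 samples for a quadratic fit")
    tree = cKDTree(sample_xy)

    out = np.empty((len(query_xy), vals.shape[1]))
    for c in range(vals.shape[1]):
        rw = np.ones(n)
        for _ in range(max(0, robust_iter)):
            fitted = _lowess_eval(tree, sample_xy, vals[:, c], sample_xy,
                                  k, rw)
            resid = vals[:, c] - fitted
            s = np.median(np.abs(resid))
            if s <= 1e-300:
                break
            u = resid / (6.0 * s)
            rw = np.clip(1.0 - u * u, 0.0, None) ** 2
        out[:, c] = _lowess_eval(tree, sample_xy, vals[:, c], query_xy, k, rw)
    return out[:, 0] if squeeze else out


def _lowess_eval(tree, sample_xy, v, queries, k, robust_w):
    n = len(sample_xy)
    dists, idx = tree.query(queries, k=k)
    if k == 1:
        dists, idx = dists[:, None], idx[:, None]
    out = np.empty(len(queries))
    for i, q in enumerate(queries):
        out[i] = _local_quadratic(sample_xy, v, q, dists[i], idx[i],
                                  robust_w, tree, n)
    return out


def _local_quadratic(sample_xy, v, q, d, idx, robust_w, tree, n,
                     _widened=False):
    dmax = d[-1]
    if dmax <= 0:
        # all neighbours coincide with the query; return their mean
        return float(np.average(v[idx], weights=robust_w[idx] + 1e-12))
    w = (1.0 - np.minimum(d / (dmax * 1.0001), 1.0) ** 3) ** 3
    w = w * robust_w[idx]
    dx = sample_xy[idx] - q
    X = np.column_stack([np.ones(len(idx)), dx[:, 0], dx[:, 1],
                         dx[:, 0] ** 2, dx[:, 0] * dx[:, 1], dx[:, 1] ** 2])
    sw = np.sqrt(w)
    coef, _, rank, _ = np.linalg.lstsq(X * sw[:, None], v[idx] * sw,
                                       rcond=None)
    if rank < 6:
        if _widened or 2 * len(idx) >= n:
            if len(idx) == n:
                raise ValueError(
                    "under-determined local quadratic fit even at full window")
            k2 = n
        else:
            k2 = min(2 * len(idx), n)
        if not _widened:
            d2, i2 = tree.query(q, k=k2)
            return _local_quadratic(sample_xy, v, q, np.atleast_1d(d2),
                                    np.atleast_1d(i2), robust_w, tree, n,
                                    _widened=True)
        raise ValueError("under-determined local quadratic fit")
    return float(coef[0])


# ---------------------------------------------------------------------------
# Mesh building
# ---------------------------------------------------------------------------

@dataclass
class MeshSpec:
    """Analysis-mesh layout: node spacing and circular region of interest.

    ``spacing`` defaults to 1/20 of the region radius when left ``None``.
    """

    radius: float
    spacing: float | None = None
    center: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.spacing is None:
            self.spacing = self.radius / 10.0
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")


@dataclass
class PlaneFrame:
    """Best-fit plane of a point cloud: origin, in-plane axes and normal."""

    origin: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    normal: np.ndarray

    def to_plane(self, X: np.ndarray) -> np.ndarray:
        d = np.atleast_2d(X) - self.origin
        return np.column_stack([d @ self.e1, d @ self.e2])

    def heights(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.origin) @ self.normal

    def to_world(self, ab: np.ndarray, z: np.ndarray) -> np.ndarray:
        ab = np.atleast_2d(ab)
        return (self.origin + ab[:, :1] * self.e1 + ab[:, 1:2] * self.e2
                + np.asarray(z)[:, None] * self.normal)


def fit_plane(points: np.ndarray) -> PlaneFrame:
    """PCA plane of a cloud; the normal is the least-variance direction."""
    points = np.asarray(points, float)
    origin = points.mean(axis=0)
    _, _, Vt = np.linalg.svd(points - origin, full_matrices=False)
    e1, e2, normal = Vt
    if np.linalg.det(np.vstack([e1, e2, normal])) < 0:
        normal = -normal
    return PlaneFrame(origin, e1, e2, normal)


def _disc_lattice(radius: float, spacing: float) -> np.ndarray:
    """Near-equilateral node layout for a disc: hex lattice + exact rim ring.

    A plain grid clipped to a circle leaves sliver triangles along the rim
    that poison the inverse-equilibrium rows; a triangular lattice with an
    explicit circular boundary ring keeps element quality uniform.
    """
    row_h = spacing * np.sqrt(3.0) / 2.0
    pts = []
    j = 0
    while j * row_h <= radius - 0.45 * spacing:
        for sj in ((j,) if j == 0 else (j, -j)):
            y = sj * row_h
            x_off = 0.5 * spacing if (sj % 2) else 0.0
            half_w = np.sqrt(max(radius ** 2 - y ** 2, 0.0))
            m = int(np.floor((half_w - 0.45 * spacing - x_off) / spacing))
            xs = x_off + np.arange(-m, m + 1) * spacing
            pts.append(np.column_stack([xs, np.full(xs.shape, y)]))
        j += 1
    inner = np.concatenate(pts)
    n_rim = max(8, int(np.ceil(2 * np.pi * radius / spacing)))
    th = np.linspace(0.0, 2 * np.pi, n_rim, endpoint=False)
    rim = radius * np.column_stack([np.cos(th), np.sin(th)])
    return np.vstack([inner, rim])


def build_frames(reference_cloud: np.ndarray,
                 tracks: list[FeatureTrack],
                 cam_left: CameraModel, cam_right: CameraModel,
                 mesh_spec: MeshSpec,
                 span: float = 0.15,
                 min_tracks: int = 20) -> tuple[TriMesh, np.ndarray]:
    """Fit the reference mesh to the cloud and advect it with the tracks.

    The reference surface is a robust LOWESS height field over the cloud's
    best-fit plane, sampled on a regular grid clipped to the circular region
    of interest and triangulated by planar Delaunay. For every frame the
    tracks are triangulated to 3D, their displacements from frame 0 are
    LOWESS-interpolated (componentwise) onto the mesh nodes, and added to the
    reference nodal positions.
    """
    if len(tracks) < min_tracks:
        raise ValueError(
            f"only {len(tracks)} surviving tracks (< {min_tracks})")
    cloud = np.asarray(reference_cloud, float)
    plane = fit_plane(cloud)
    ab_cloud = plane.to_plane(cloud)
    z_cloud = plane.heights(cloud)

    center = (np.asarray(mesh_spec.center, float)
              if mesh_spec.center is not None else ab_cloud.mean(axis=0))
    nodes_ab = _disc_lattice(mesh_spec.radius, mesh_spec.spacing) + center
    tri = Delaunay(nodes_ab)
    z_nodes = lowess_surface(ab_cloud, z_cloud, nodes_ab, span=span)
    ref_nodes = plane.to_world(nodes_ab, z_nodes)
    mesh = TriMesh(ref_nodes, tri.simplices)

    n_frames = tracks[0].n_frames
    L = np.stack([t.left for t in tracks])   # (n_tracks, n_frames, 2)
    R = np.stack([t.right for t in tracks])
    track_pos = np.stack([
        triangulate_points(L[:, f], R[:, f], cam_left, cam_right)
        for f in range(n_frames)
    ])                                        # (n_frames, n_tracks, 3)
    track_ab0 = plane.to_plane(track_pos[0])

    frames = np.empty((n_frames, mesh.n_nodes, 3))
    frames[0] = ref_nodes
    for f in range(1, n_frames):
        disp = track_pos[f] - track_pos[0]
        nodal_disp = lowess_surface(track_ab0, disp, nodes_ab, span=span)
        frames[f] = ref_nodes + nodal_disp
    return mesh, frames
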