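"""Synthetic inflation data with exact ground truth.

Every downstream stage (surface reconstruction, kinematics, inverse stress,
constitutive identification) is exercised on data generated here, so each
generator carries its exact per-element ground truth.

The forward model for inflation is a uniformly stretched spherical cap: a
clamped circular membrane of radius ``r0`` is represented by a cap of a
sphere of radius ``r0`` that inflates by pure radial scaling.  For an
incompressible Ogden material under equibiaxial stretch ``lam`` the Cauchy
stress is ``sigma = mu (lam**alpha - lam**(-2 alpha))``, the thickness thins
as ``h = h0 / lam**2`` and the Laplace force balance gives the chamber
pressure ``p = 2 h sigma / r`` with current radius ``r = lam r0``.  This is
not a clamped-cap boundary-value solution: equilibrium holds exactly only
away from the rim, and oracle comparisons therefore restrict to interior
elements.

Default study conditions mirror the inflation experiment being emulated:
30 mm diameter specimen holder (r0 = 15 mm), initial thickness 375 um, Ogden
parameters mu = 234 kPa and alpha = 8.19, a pressure ramp of 2.9 kPa/s, and
one stereo frame per second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh

from .mesh import InflationDataset, TriMesh
from .stereo import CameraModel

__all__ = [
    "SphereInflationSpec",
    "StereoRig",
    "NoiseSpec",
    "simulate_sphere_inflation",
    "impose_deformation",
    "render_feature_tracks",
    "default_rig",
    "ogden_equibiaxial_stress",
    "sphere_pressure",
    "spherical_cap_mesh",
]

PRESSURE_RAMP_PA_S = 2900.0  # chamber pressurization rate being emulated


def _default_schedule() -> np.ndarray:
    # ~50 frames (one per second) up to a stretch where the chamber pressure
    # reaches the ~164 kPa burst level of the emulated tests
    return np.linspace(1.0, 1.65, 50)


@dataclass
class SphereInflationSpec:
    """Study conditions for the analytic spherical-cap inflation."""

    clamp_radius: float = 15e-3          # r0 (m)
    initial_thickness: float = 375e-6    # h0 (m)
    mu: float = 234e3                    # Ogden mu (Pa)
    alpha: float = 8.19                  # Ogden alpha (-)
    stretch_schedule: np.ndarray = field(default_factory=_default_schedule)
    mesh_resolution: int = 300           # target node count of the cap
    cap_fraction: float = 0.5            # fraction of the sphere meshed

    def __post_init__(self) -> None:
        self.stretch_schedule = np.asarray(self.stretch_schedule, float)
        if self.clamp_radius <= 0 or self.initial_thickness <= 0:
            raise ValueError("clamp_radius and initial_thickness must be > 0")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")
        lam = self.stretch_schedule
        if lam.ndim != 1 or lam.size == 0:
            raise ValueError("stretch_schedule must be a 1D sequence")
        if not np.isclose(lam[0], 1.0):
            raise ValueError("stretch_schedule must start at 1")
        if np.any(lam < 1.0):
            raise ValueError("non-physical schedule: stretches must be >= 1")
        if np.any(np.diff(lam) < 0):
            raise ValueError("stretch_schedule must be non-decreasing")
        if not 0 < self.cap_fraction <= 0.5:
            raise ValueError("cap_fraction must be in (0, 0.5]")


@dataclass
class StereoRig:
    """Two calibrated cameras observing the membrane."""

    left: CameraModel
    right: CameraModel

    def __post_init__(self) -> None:
        if np.allclose(self.left.center, self.right.center):
            raise ValueError("camera centres must be distinct")

    @property
    def baseline(self) -> float:
        return float(np.linalg.norm(self.left.center - self.right.center))


@dataclass
class NoiseSpec:
    """Measurement degradation applied to rendered feature tracks.

    ``dropout_rate`` is the probability that a track is truncated partway
    (emulating speckle washout by leaking water droplets); ``outlier_rate``
    the probability that a track receives a gross constant pixel offset of
    ``20 * pixel_sigma`` from a random frame onward, so that the
    mean-velocity filter has something to catch.
    """

    pixel_sigma: float = 0.0
    dropout_rate: float = 0.0
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_sigma < 0:
            raise ValueError("pixel_sigma must be >= 0")
        for name in ("dropout_rate", "outlier_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


# ---------------------------------------------------------------------------
# Constitutive closed forms
# ---------------------------------------------------------------------------

def ogden_equibiaxial_stress(lam, mu: float, alpha: float):
    """Equibiaxial in-plane Cauchy stress of an incompressible Ogden sheet."""
    lam = np.asarray(lam, float)
    return mu * (lam ** alpha - lam ** (-2.0 * alpha))


def sphere_pressure(lam, spec: SphereInflationSpec):
    """Chamber pressure of the uniformly stretched cap at stretch ``lam``."""
    lam = np.asarray(lam, float)
    sigma = ogden_equibiaxial_stress(lam, spec.mu, spec.alpha)
    h = spec.initial_thickness / lam ** 2
    r = lam * spec.clamp_radius
    return 2.0 * h * sigma / r


# ---------------------------------------------------------------------------
# Meshing
# ---------------------------------------------------------------------------

def spherical_cap_mesh(radius: float, cap_fraction: float = 0.5,
                       target_nodes: int = 300) -> TriMesh:
    """Icosphere-derived triangulation of a spherical cap.

    The cap keeps the elements of a subdivided icosphere whose nodes all lie
    above ``z = (1 - 2 cap_fraction) * radius`` (a cap holding the requested
    fraction of the sphere's area), so the rim is slightly ragged but the
    triangles are near-equilateral.
    """
    subdiv = 1
    while cap_fraction * (10 * 4 ** subdiv + 2) < target_nodes and subdiv < 7:
        subdiv += 1
    ico = _trimesh.creation.icosphere(subdivisions=subdiv, radius=radius)
    z_min = (1.0 - 2.0 * cap_fraction) * radius
    keep = np.flatnonzero(
        (ico.vertices[:, 2] >= z_min - 1e-9 * radius)[ico.faces].all(axis=1))
    faces = ico.faces[keep]
    used = np.unique(faces)
    remap = -np.ones(len(ico.vertices), dtype=np.intp)
    remap[used] = np.arange(len(used))
    return TriMesh(np.array(ico.vertices[used]), remap[faces])


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def simulate_sphere_inflation(spec: SphereInflationSpec) -> InflationDataset:
    """Generate an inflation dataset from the analytic spherical-cap model.

    Frame ``k`` scales the reference cap radially by the scheduled stretch;
    ground truth per element and frame (in-plane deformation gradient,
    principal stretches, current thickness, principal Cauchy stresses) is
    attached, exact by construction.
    """
    mesh = spherical_cap_mesh(spec.clamp_radius, spec.cap_fraction,
                              spec.mesh_resolution)
    mesh.thickness = np.full(mesh.n_elements, spec.initial_thickness)
    lam = spec.stretch_schedule
    n_frames = len(lam)
    m = mesh.n_elements

    frames = lam[:, None, None] * mesh.nodes[None]
    pressures = sphere_pressure(lam, spec)
    times = pressures / PRESSURE_RAMP_PA_S

    eye = np.eye(2)
    F = lam[:, None, None, None] * np.broadcast_to(eye, (n_frames, m, 2, 2))
    sig = ogden_equibiaxial_stress(lam, spec.mu, spec.alpha)
    ground_truth = {
        "F": F,
        "lambda1": np.repeat(lam[:, None], m, axis=1),
        "lambda2": np.repeat(lam[:, None], m, axis=1),
        "h": np.repeat((spec.initial_thickness / lam ** 2)[:, None], m,
                       axis=1),
        "sigma1": np.repeat(sig[:, None], m, axis=1),
        "sigma2": np.repeat(sig[:, None], m, axis=1),
        "mu": spec.mu,
        "alpha": spec.alpha,
    }
    return InflationDataset(mesh=mesh, frames=frames, pressures=pressures,
                            times=times, ground_truth=ground_truth)


def impose_deformation(mesh: TriMesh, mapping, n_frames: int) -> np.ndarray:
    """Frame sequence interpolating linearly from identity to ``mapping``.

    Frame ``k`` (k = 0..n_frames) holds ``x + (k / n_frames) * (mapping(x)
    - x)`` at every node, so the final frame is the mapping itself.  For an
    affine mapping the ground-truth deformation gradient of frame ``k`` is
    the same interpolation of the mapping's matrix.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    target = np.asarray(mapping(mesh.nodes), float)
    if target.shape != mesh.nodes.shape:
        raise ValueError("mapping must return one 3D point per node")
    fracs = np.arange(n_frames + 1) / n_frames
    frames = mesh.nodes[None] + fracs[:, None, None] * (target - mesh.nodes)
    # flag degenerate geometry anywhere in the sequence
    for k in (n_frames,):
        tri = frames[k][mesh.triangles]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        if np.any(areas <= 1e-16 * np.max(areas, initial=1.0)):
            bad = np.flatnonzero(areas <= 1e-16 * np.max(areas)).tolist()
            raise ValueError(f"mapping degenerates elements {bad}")
    return frames


def default_rig(distance: float = 0.25, baseline: float = 0.1,
                focal_px: float = 4000.0,
                image_size: tuple[int, int] = (2048, 2048)) -> StereoRig:
    """Symmetric verging stereo rig looking down the -z axis at the origin.

    Both cameras sit at height ``distance`` above the world origin, separated
    by ``baseline`` along x, and verge so their optical axes intersect at the
    origin (where the membrane apex region sits).
    """
    cx, cy = image_size[0] / 2.0, image_size[1] / 2.0
    K = np.array([[focal_px, 0.0, cx], [0.0, focal_px, cy], [0.0, 0.0, 1.0]])
    rigs = []
    for sx in (-1.0, +1.0):
        C = np.array([sx * baseline / 2.0, 0.0, distance])
        # optical axis from C towards the origin
        zc = -C / np.linalg.norm(C)
        up = np.array([0.0, 1.0, 0.0])
        xc = np.cross(up, zc)
        xc /= np.linalg.norm(xc)
        yc = np.cross(zc, xc)
        R = np.vstack([xc, yc, zc])
        t = -R @ C
        rigs.append(CameraModel(K, R, t))
    return StereoRig(left=rigs[0], right=rigs[1])


def render_feature_tracks(mesh: TriMesh, frames: np.ndarray, rig: StereoRig,
                          noise: NoiseSpec, n_features: int
                          ) -> tuple[list, np.ndarray]:
    """Sample surface features, advect them with the frames, project them.

    Features are sampled uniformly by area on the reference mesh and advected
    through every frame by their barycentric coordinates.  Each feature is
    projected through both cameras; Gaussian pixel noise, dropout (track
    truncated at a random frame) and gross outliers (constant pixel offset of
    ``20 * pixel_sigma`` in a random direction from a random frame onward)
    are then applied per :class:`NoiseSpec`.

    Returns
    -------
    tracks : list of FeatureTrack
    true_positions : (n_frames, n_features, 3) array of exact 3D tracks.
    """
    from .stereo import FeatureTrack

    frames = np.asarray(frames, float)
    n_frames = frames.shape[0]
    rng = np.random.default_rng(noise.seed)

    _, areas = mesh.element_normals_areas()
    elem = rng.choice(mesh.n_elements, size=n_features, p=areas / areas.sum())
    r1, r2 = rng.random(n_features), rng.random(n_features)
    s = np.sqrt(r1)
    bary = np.column_stack([1 - s, s * (1 - r2), s * r2])

    tri_idx = mesh.triangles[elem]                  # (n_features, 3)
    true_pos = np.einsum("fkpc,kp->fkc", frames[:, tri_idx], bary)

    tracks = []
    for j in range(n_features):
        pix_l = rig.left.project(true_pos[:, j])
        pix_r = rig.right.project(true_pos[:, j])
        if noise.pixel_sigma > 0:
            pix_l = pix_l + rng.normal(0, noise.pixel_sigma, pix_l.shape)
            pix_r = pix_r + rng.normal(0, noise.pixel_sigma, pix_r.shape)
        valid = np.ones(n_frames, dtype=bool)
        if noise.dropout_rate > 0 and rng.random() < noise.dropout_rate:
            cut = rng.integers(1, n_frames)
            valid[cut:] = False
        if noise.outlier_rate > 0 and rng.random() < noise.outlier_rate:
            start = rng.integers(1, n_frames)
            theta = rng.uniform(0, 2 * np.pi)
            off = 20.0 * noise.pixel_sigma * np.array(
                [np.cos(theta), np.sin(theta)])
            pix_l[start:] += off
            pix_r[start:] += off
        tracks.append(FeatureTrack(j, pix_l, pix_r, valid))
    return tracks, true_pos
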