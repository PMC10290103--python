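"""Patch orientation and 2D projection matrices (EM, SEM, CEM, shape).

A surface patch (points within a 9 Angstrom sphere centred on a surface
point) is rotated so that its best-fit plane is the x-y plane, projected,
and binned onto a square pixel grid (25x25 by default):

* EM   — Electrostatic Matrix: mean electrostatic potential per pixel.
* SEM  — Simplified EM: the sign (+1/-1) of each EM pixel.
* CEM  — Confined EM: EM clipped to [-30, +30] so the field is bounded and
         Zernike-expandable.
* SHAPE — mean distance r from the patch points to a cone origin C on the
         z-axis, with C placed so the half-angle of the cone subtending the
         patch is 45 degrees.

Two orientation protocols exist.  Single-patch: each patch gets its own
plane fit, with the solvent-exposed side toward +z ("up") or -z ("down");
used for random/decoy patches and for Zernike comparisons.  Pair: both
patches of an interacting pair receive one common rotation taking the mean
of (normals of A) - (normals of B) to +z, preserving the spatial
correspondence of facing points; required for the pixel-wise F score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "OrientedPatch",
    "ProjectionMatrix",
    "ConeOrigin",
    "fit_plane",
    "orient_single",
    "orient_pair",
    "cone_origin",
    "project_shape",
    "project_potential",
    "em_to_sem",
    "em_to_cem",
]

DEFAULT_PIXELS = 25
DEFAULT_CEM_CAP = 30.0
CONE_HALF_ANGLE_DEG = 45.0


@dataclass
class OrientedPatch:
    """Patch coordinates after rotation into the projection frame."""

    points: np.ndarray  # (n, 3), rotated and centred
    normals: np.ndarray  # (n, 3), rotated
    values: Optional[np.ndarray] = None  # per-point potential
    orientation: str = "up"  # 'up' | 'down'
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            if len(self.values) != len(self.points):
                raise ValueError("values and points length mismatch")
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if self.orientation not in ("up", "down"):
            raise ValueError(f"orientation must be 'up' or 'down', got {self.orientation!r}")


@dataclass
class ProjectionMatrix:
    """Square pixel grid with a validity mask.

    ``disk_scale`` is the planar radius (Angstrom) mapped to unit-disk
    radius 1 in the Zernike expansion; the grid spans
    [-disk_scale, disk_scale]^2.
    """

    kind: str  # 'EM' | 'SEM' | 'CEM' | 'SHAPE'
    grid: np.ndarray
    mask: np.ndarray
    pixel_size: float
    disk_scale: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.kind not in ("EM", "SEM", "CEM", "SHAPE"):
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.grid.shape != self.mask.shape or self.grid.ndim != 2:
            raise ValueError("grid and mask must be equal-shape 2D arrays")

    @property
    def n_pixels(self) -> int:
        return self.grid.shape[0]


@dataclass
class ConeOrigin:
    """Apex C = (0, 0, h) of the 45-degree viewing cone over a patch."""

    C: np.ndarray
    theta: float = CONE_HALF_ANGLE_DEG

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)


class DegeneratePatchError(ValueError):
    """Raised when a patch cannot support a plane fit or cone solution."""


def fit_plane(points: np.ndarray, reference_normal: Optional[np.ndarray] = None):
    """Total-least-squares plane through ``points``.

    Returns (unit normal, offset) with the plane {x : n.x = offset}.  The
    normal sign is chosen to align with ``reference_normal`` (typically the
    patch's mean surface normal) when given.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise DegeneratePatchError("plane fit needs at least 3 points in 3D")
    centroid = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise DegeneratePatchError("points are collinear; plane fit is degenerate")
    normal = vt[2]
    if reference_normal is not None and np.dot(normal, reference_normal) < 0:
        normal = -normal
    return normal, float(np.dot(normal, centroid))


def _rotation_to_z(v: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector v to +z (Rodrigues)."""
    v = np.asarray(v, dtype=float)
    v = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, z))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 degrees about x
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(v, z)
    axis /= np.linalg.norm(axis)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    s = np.sqrt(1.0 - c * c)
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def _mean_normal(normals: np.ndarray) -> np.ndarray:
    m = np.asarray(normals, dtype=float).mean(axis=0)
    norm = np.linalg.norm(m)
    if norm < 1e-9:
        raise DegeneratePatchError("mean normal vanishes; orientation undefined")
    return m / norm


def orient_single(
    points: np.ndarray,
    normals: np.ndarray,
    values: Optional[np.ndarray] = None,
    direction: str = "up",
) -> OrientedPatch:
    """Rotate one patch so its fitted-plane normal lies along +z or -z.

    The patch centroid is moved to the origin.  'down' applies a further
    180-degree rotation about the x-axis, so z-coordinates are negated
    relative to 'up'.
    """
    pts = np.asarray(points, dtype=float)
    nrm = np.asarray(normals, dtype=float)
    plane_normal, _ = fit_plane(pts, reference_normal=_mean_normal(nrm))
    Z = np.diag([1.0, 1.0, -1.0])
    if direction == "up":
        R = _rotation_to_z(plane_normal)
    elif direction == "down":
        if plane_normal[2] < 0:
            # minimal rotation in the z-mirrored frame: a patch already
            # facing down keeps its in-plane pose, so facing patches of a
            # pair stay pixel-aligned
            R = Z @ _rotation_to_z(Z @ plane_normal) @ Z
        else:
            # z-reflection of the 'up' frame: down(patch) is exactly the
            # z-negated up(patch)
            R = Z @ _rotation_to_z(plane_normal)
    else:
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    centroid = pts.mean(axis=0)
    return OrientedPatch(
        points=(pts - centroid) @ R.T,
        normals=nrm @ R.T,
        values=None if values is None else np.asarray(values, dtype=float),
        orientation=direction,
        rotation=R,
    )


def orient_pair(
    points_A: np.ndarray,
    normals_A: np.ndarray,
    points_B: np.ndarray,
    normals_B: np.ndarray,
    values_A: Optional[np.ndarray] = None,
    values_B: Optional[np.ndarray] = None,
) -> tuple[OrientedPatch, OrientedPatch]:
    """Common rotation for an interacting pair, preserving correspondence.

    The axis v = normalize(mean normal of A - mean normal of B) is taken to
    +z; A ends up 'up' and B 'down'.  One translation (the midpoint of the
    two patch centroids) is removed from both, so facing points keep their
    x-y correspondence.
    """
    nA = np.asarray(normals_A, dtype=float).mean(axis=0)
    nB = np.asarray(normals_B, dtype=float).mean(axis=0)
    v = nA - nB
    norm = np.linalg.norm(v)
    if norm < 1e-9:
        raise DegeneratePatchError(
            "mean normals of the two patches cancel; pair orientation undefined"
        )
    R = _rotation_to_z(v / norm)
    mid = 0.5 * (
        np.asarray(points_A, dtype=float).mean(axis=0)
        + np.asarray(points_B, dtype=float).mean(axis=0)
    )
    opA = OrientedPatch(
        points=(np.asarray(points_A, dtype=float) - mid) @ R.T,
        normals=np.asarray(normals_A, dtype=float) @ R.T,
        values=None if values_A is None else np.asarray(values_A, dtype=float),
        orientation="up",
        rotation=R,
    )
    opB = OrientedPatch(
        points=(np.asarray(points_B, dtype=float) - mid) @ R.T,
        normals=np.asarray(normals_B, dtype=float) @ R.T,
        values=None if values_B is None else np.asarray(values_B, dtype=float),
        orientation="down",
        rotation=R,
    )
    return opA, opB


def cone_origin(op: OrientedPatch, tol: float = 1e-6, max_radius_factor: float = 10.0) -> ConeOrigin:
    """Place C = (0, 0, h) so the largest secant angle to the patch is 45 deg.

    The largest angle between the -z axis and any secant C->point decreases
    monotonically in h, so h is found by bisection to ``tol`` radians.
    """
    pts = op.points
    rho = np.hypot(pts[:, 0], pts[:, 1])
    zmax = pts[:, 2].max()
    target = np.deg2rad(CONE_HALF_ANGLE_DEG)

    def max_angle(h: float) -> float:
        return float(np.max(np.arctan2(rho, h - pts[:, 2])))

    lo = zmax + 1e-9
    hi = zmax + max_radius_factor * max(rho.max(), 1e-9)
    if max_angle(hi) > target:
        raise DegeneratePatchError("no 45-degree cone apex above the patch in range")
    if max_angle(lo) < target:
        # patch is a single column on the axis; any apex sees < 45 degrees
        raise DegeneratePatchError("patch subtends less than 45 degrees at any apex")
    h = 0.5 * (lo + hi)
    for _ in range(200):
        h = 0.5 * (lo + hi)
        angle = max_angle(h)
        if abs(angle - target) <= tol:
            break
        if angle > target:
            lo = h
        else:
            hi = h
    return ConeOrigin(C=np.array([0.0, 0.0, h]))


def _bin_mean(
    xy: np.ndarray, values: np.ndarray, n_pixels: int, disk_scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Mean of ``values`` per pixel of a grid spanning [-s, s]^2."""
    s = disk_scale
    width = 2.0 * s / n_pixels
    ix = np.clip(((xy[:, 0] + s) / width).astype(int), 0, n_pixels - 1)
    iy = np.clip(((xy[:, 1] + s) / width).astype(int), 0, n_pixels - 1)
    total = np.zeros((n_pixels, n_pixels))
    count = np.zeros((n_pixels, n_pixels))
    np.add.at(total, (ix, iy), values)
    np.add.at(count, (ix, iy), 1.0)
    mask = count > 0
    grid = np.zeros_like(total)
    grid[mask] = total[mask] / count[mask]
    return grid, mask


def _disk_scale(op: OrientedPatch) -> float:
    rho = np.hypot(op.points[:, 0], op.points[:, 1])
    s = float(rho.max())
    if s <= 0:
        raise DegeneratePatchError("patch has zero planar extent")
    return s


def project_shape(
    op: OrientedPatch,
    cone: ConeOrigin,
    n_pixels: int = DEFAULT_PIXELS,
    disk_scale: Optional[float] = None,
) -> ProjectionMatrix:
    """SHAPE matrix: mean distance r from patch points to the cone apex C."""
    s = _disk_scale(op) if disk_scale is None else float(disk_scale)
    r = np.linalg.norm(op.points - cone.C, axis=1)
    grid, mask = _bin_mean(op.points[:, :2], r, n_pixels, s)
    return ProjectionMatrix("SHAPE", grid, mask, 2.0 * s / n_pixels, s)


def project_potential(
    op: OrientedPatch,
    n_pixels: int = DEFAULT_PIXELS,
    disk_scale: Optional[float] = None,
) -> ProjectionMatrix:
    """EM: mean electrostatic potential of the points projected per pixel."""
    if op.values is None:
        raise ValueError("oriented patch carries no potential values")
    s = _disk_scale(op) if disk_scale is None else float(disk_scale)
    grid, mask = _bin_mean(op.points[:, :2], op.values, n_pixels, s)
    return ProjectionMatrix("EM", grid, mask, 2.0 * s / n_pixels, s)


def fill_masked_pixels(matrix: ProjectionMatrix) -> ProjectionMatrix:
    """Fill in-disk masked-out pixels with iterated 8-neighbour means.

    Sparse sampling leaves empty pixels inside the projection disk;
    leaving them as zeros punches holes of the field's full magnitude
    into an otherwise smooth matrix, which dominates the Zernike
    spectrum and breaks rotation stability of the descriptor.  Filling
    by neighbour means extends the field smoothly; the returned matrix
    has those pixels masked-in.  Intended for matrices feeding the
    Zernike expansion; the F score keeps the raw mask semantics.
    """
    from scipy import ndimage

    g = matrix.grid.copy()
    m = matrix.mask.copy()
    G = g.shape[0]
    c = (np.arange(G) + 0.5) * (2.0 / G) - 1.0
    X, Y = np.meshgrid(c, c, indexing="ij")
    # include rim pixels whose center is just outside the disk but whose
    # area still contributes to the expansion
    in_disk = np.hypot(X, Y) <= 1.0 + 1.0 / G
    kernel = np.ones((3, 3))
    while np.any(in_disk & ~m):
        total = ndimage.convolve(np.where(m, g, 0.0), kernel, mode="constant")
        count = ndimage.convolve(m.astype(float), kernel, mode="constant")
        newly = in_disk & ~m & (count > 0)
        if not np.any(newly):
            break
        g[newly] = total[newly] / count[newly]
        m |= newly
    return ProjectionMatrix(matrix.kind, g, m, matrix.pixel_size, matrix.disk_scale)


def em_to_sem(em: ProjectionMatrix) -> ProjectionMatrix:
    """SEM: sign of each EM pixel; exact zeros are masked (sign undefined)."""
    if em.kind != "EM":
        raise ValueError(f"expected an EM, got {em.kind}")
    mask = em.mask & (em.grid != 0.0)
    grid = np.zeros_like(em.grid)
    grid[mask] = np.sign(em.grid[mask])
    return ProjectionMatrix("SEM", grid, mask, em.pixel_size, em.disk_scale)


def em_to_cem(em: ProjectionMatrix, cap: float = DEFAULT_CEM_CAP) -> ProjectionMatrix:
    """CEM: EM clipped to [-cap, +cap] (cap in the potential's input units)."""
    if em.kind not in ("EM", "CEM"):
        raise ValueError(f"expected an EM, got {em.kind}")
    grid = np.clip(em.grid, -cap, cap)
    grid[~em.mask] = 0.0
    return ProjectionMatrix("CEM", grid, em.mask.copy(), em.pixel_size, em.disk_scale)
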