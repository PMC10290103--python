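"""Synthetic facing-surface complexes with known ground truth.

Real inputs to the pipeline are DMS point clouds and Poisson-Boltzmann
potential grids; neither can be regenerated offline, so this module
produces physically shaped stand-ins with every ground-truth quantity the
tests need: two facing sheets sampled at ~5 points per square Angstrom
with outward unit normals, geometric complementarity (Gaussian bumps on
one sheet matched by dents on the other, constant vertical gap), and a
smooth random potential field that is sign-inverted across the interface
except on a controllable fraction ``sign_agreement_p`` of contiguous
regions.  That fraction is the ground truth the pixel-level F score
should recover, and it is set exactly (by an empirical quantile of the
flip field) on every realization.

The fields are deliberately simple: sums of random-centre Gaussian blobs,
stationary and zero-mean, with amplitudes scaled so a tunable share of
potential values exceeds the +-30 CEM cap.  What they do not emulate:
curvature of real globular proteins, chemistry-driven potential
structure, or surface self-occlusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .patch_projection import ProjectionMatrix
from .surface_io import (
    MolecularSurface,
    PotentialGrid,
    PotentialSurface,
    RESIDUE_TAG_DTYPE,
    write_dms,
    write_dx,
)
from .composition import AMINO_ACIDS

__all__ = [
    "GeneratorConfig",
    "gen_complex",
    "gen_random_sem_pair",
    "gen_rotated_copy",
    "write_complex_files",
]

DEFAULT_SEED = 20230623


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic benchmark.

    density and patch_radius mirror the real pipeline's sampling (5 points
    per square Angstrom, 9 Angstrom patches).  bump_amplitude 1.5 Angstrom
    and correlation length ~2.5 Angstrom give gentle, resolvable relief;
    noise_sigma is per-point jitter along z.  potential_scale 15 (solver
    units) makes a minority of potential values exceed the +-30 CEM cap so
    clipping is exercised.  gap is the vertical distance between the
    facing sheets (2 Angstrom, well inside the 6 Angstrom interface
    cutoff).
    """

    density: float = 5.0
    patch_radius: float = 9.0
    bump_amplitude: float = 1.5
    noise_sigma: float = 0.1
    sign_agreement_p: float = 0.2
    potential_scale: float = 15.0
    gap: float = 2.0
    seed: int = DEFAULT_SEED
    sheet_margin: float = 3.0
    blob_sigma: float = 2.5
    flip_sigma: float = 4.0

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        if not 0.0 <= self.sign_agreement_p <= 1.0:
            raise ValueError("sign_agreement_p must lie in [0, 1]")
        if self.gap <= 0:
            raise ValueError("gap must be positive")

    @property
    def half_side(self) -> float:
        return self.patch_radius + self.sheet_margin


class _BlobField:
    """Sum of isotropic 2D Gaussians; smooth, stationary, zero-mean.

    Centres are drawn from a 3-sigma margin beyond the sheet so the field
    statistics stay uniform out to the sheet edge (no edge-variance drop),
    with the blob count scaled up to keep the interior density fixed.
    """

    def __init__(self, rng, half_side: float, sigma: float, n_blobs: int, scale: float):
        ext = half_side + 3.0 * sigma
        n_blobs = max(1, int(round(n_blobs * (ext / half_side) ** 2)))
        self.centers = rng.uniform(-ext, ext, size=(n_blobs, 2))
        self.amps = rng.normal(0.0, scale, size=n_blobs)
        self.sigma = sigma

    def __call__(self, xy: np.ndarray) -> np.ndarray:
        d2 = ((xy[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return (self.amps[None, :] * np.exp(-d2 / (2.0 * self.sigma**2))).sum(axis=1)

    def gradient(self, xy: np.ndarray) -> np.ndarray:
        diff = xy[:, None, :] - self.centers[None, :, :]
        d2 = (diff**2).sum(axis=2)
        g = self.amps[None, :] * np.exp(-d2 / (2.0 * self.sigma**2))
        return -(g[:, :, None] * diff / self.sigma**2).sum(axis=1)


def _sheet_xy(rng, half_side: float, density: float) -> np.ndarray:
    spacing = 1.0 / np.sqrt(density)
    axis = np.arange(-half_side, half_side + spacing / 2, spacing)
    X, Y = np.meshgrid(axis, axis, indexing="ij")
    xy = np.column_stack([X.ravel(), Y.ravel()])
    xy += rng.uniform(-0.3 * spacing, 0.3 * spacing, size=xy.shape)
    return xy


def _residue_tags(xy: np.ndarray, chain: str, rng, cell: float = 2.0) -> np.ndarray:
    """Group points into 2 Angstrom cells, one pseudo-residue per cell."""
    ix = np.floor(xy[:, 0] / cell).astype(int)
    iy = np.floor(xy[:, 1] / cell).astype(int)
    keys = {(a, b) for a, b in zip(ix, iy)}
    names = {k: AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))] for k in sorted(keys)}
    nums = {k: str(i + 1) for i, k in enumerate(sorted(keys))}
    tags = np.empty(len(xy), dtype=RESIDUE_TAG_DTYPE)
    for j, (a, b) in enumerate(zip(ix, iy)):
        tags[j] = (chain, nums[(a, b)], names[(a, b)])
    return tags


def gen_complex(config: GeneratorConfig | None = None):
    """Generate a facing complementary pair of potential surfaces.

    Returns ``(psurf_A, psurf_B, ground_truth)``.  Sheet A carries the
    bump relief with outward normals toward +z; sheet B replicates the
    relief shifted up by ``gap`` with outward normals toward -z (its solid
    side is above), so A's bumps face matching dents in B.  B's potential
    is the negation of A's field except on contiguous flip-back regions
    covering exactly a fraction ``sign_agreement_p`` of B's points.

    ground_truth keys: ``p``, ``flip_mask_B``, ``phi_at_A``, ``phi_at_B``
    (A's field evaluated at B's planar positions), ``center_A``,
    ``center_B`` (patch centre coordinates nearest the sheet middle),
    ``height_field``, ``potential_field``, ``flip_field``,
    ``flip_threshold``, ``config``.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    hs = config.half_side
    area = (2 * hs) ** 2

    height = _BlobField(
        rng, hs, config.blob_sigma,
        n_blobs=max(4, int(area / 40)), scale=config.bump_amplitude,
    )
    phi = _BlobField(
        rng, hs, config.blob_sigma,
        n_blobs=max(6, int(area / 20)), scale=config.potential_scale,
    )
    flip = _BlobField(rng, hs, config.flip_sigma, n_blobs=max(6, int(area / 30)), scale=1.0)

    def build_side(chain: str, up: bool):
        xy = _sheet_xy(rng, hs, config.density)
        z = height(xy)
        if config.noise_sigma > 0:
            z = z + rng.normal(0.0, config.noise_sigma, size=len(xy))
        grad = height.gradient(xy)
        if up:
            normals = np.column_stack([-grad[:, 0], -grad[:, 1], np.ones(len(xy))])
        else:
            z = z + config.gap
            normals = np.column_stack([grad[:, 0], grad[:, 1], -np.ones(len(xy))])
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
        points = np.column_stack([xy, z])
        tags = _residue_tags(xy, chain, rng)
        return xy, MolecularSurface(points, normals, tags, density=config.density)

    xy_A, surf_A = build_side("A", up=True)
    xy_B, surf_B = build_side("B", up=False)

    phi_A = phi(xy_A)
    phi_at_B = phi(xy_B)
    flip_vals = flip(xy_B)
    p = config.sign_agreement_p
    if p <= 0.0:
        flip_mask = np.zeros(len(xy_B), dtype=bool)
        threshold = np.inf
    elif p >= 1.0:
        flip_mask = np.ones(len(xy_B), dtype=bool)
        threshold = -np.inf
    else:
        # the agreement fraction is the ground truth of the interacting
        # region, so the quantile is taken over the central patch area
        # (the flip field extends smoothly beyond it via the threshold)
        central = np.hypot(xy_B[:, 0], xy_B[:, 1]) <= config.patch_radius
        central_vals = flip_vals[central]
        threshold = float(np.quantile(central_vals, 1.0 - p))
        flip_mask = flip_vals >= threshold
        # exact fraction on the central region: trim quantile ties
        excess = int((flip_mask & central).sum()) - int(round(p * central.sum()))
        if excess > 0:
            ties = np.flatnonzero(flip_mask & central)
            order = np.argsort(flip_vals[ties], kind="stable")
            flip_mask[ties[order[:excess]]] = False
    phi_B = np.where(flip_mask, phi_at_B, -phi_at_B)

    psurf_A = PotentialSurface(surf_A, phi_A)
    psurf_B = PotentialSurface(surf_B, phi_B)
    center_A = surf_A.points[int(np.argmin(np.hypot(xy_A[:, 0], xy_A[:, 1])))]
    center_B = surf_B.points[int(np.argmin(np.hypot(xy_B[:, 0], xy_B[:, 1])))]
    ground_truth = {
        "p": p,
        "flip_mask_B": flip_mask,
        "phi_at_A": phi_A,
        "phi_at_B": phi_at_B,
        "center_A": center_A.copy(),
        "center_B": center_B.copy(),
        "height_field": height,
        "potential_field": phi,
        "flip_field": flip,
        "flip_threshold": threshold,
        "config": config,
    }
    return psurf_A, psurf_B, ground_truth


def gen_random_sem_pair(
    p_same: float, shape: tuple[int, int] = (25, 25), rng=None
) -> tuple[ProjectionMatrix, ProjectionMatrix]:
    """Pair of iid +-1 sign matrices agreeing per pixel with prob p_same.

    The first matrix is iid equiprobable +-1; the second copies each pixel
    with probability ``p_same`` and flips it otherwise, so the expected F
    score equals p_same exactly (binomial null of the pixel comparison).
    """
    if not 0.0 <= p_same <= 1.0:
        raise ValueError("p_same must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    a = rng.choice([-1.0, 1.0], size=shape)
    agree = rng.random(size=shape) < p_same
    b = np.where(agree, a, -a)
    mask = np.ones(shape, dtype=bool)
    px = 2.0 / shape[0]
    return (
        ProjectionMatrix("SEM", a, mask, px, 1.0),
        ProjectionMatrix("SEM", b, mask.copy(), px, 1.0),
    )


def gen_rotated_copy(points, normals, values=None, rotation=None, rng=None):
    """Rigidly rotated copy of a patch's points and normals.

    ``rotation`` may be a 3x3 matrix or ``(axis, angle_rad)``; if omitted
    a uniform random rotation is drawn from ``rng``.  Values (per-point
    potentials) are carried over unchanged.  Returns
    ``(points, normals, values, R)``.
    """
    from scipy.spatial.transform import Rotation

    if rotation is None:
        R = Rotation.random(rng=np.random.default_rng(rng)).as_matrix()
    elif isinstance(rotation, tuple):
        axis, angle = rotation
        axis = np.asarray(axis, dtype=float)
        R = Rotation.from_rotvec(angle * axis / np.linalg.norm(axis)).as_matrix()
    else:
        R = np.asarray(rotation, dtype=float)
    pts = np.asarray(points, dtype=float) @ R.T
    nrm = np.asarray(normals, dtype=float) @ R.T
    vals = None if values is None else np.array(values, dtype=float)
    return pts, nrm, vals, R


def _field_grid(config: GeneratorConfig, value_fn, z_range: tuple[float, float],
                spacing: float = 0.6) -> PotentialGrid:
    hs = config.half_side + 1.0
    xs = np.arange(-hs, hs + spacing / 2, spacing)
    zs = np.arange(z_range[0], z_range[1] + spacing / 2, spacing)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    plane = value_fn(np.column_stack([X.ravel(), Y.ravel()])).reshape(X.shape)
    values = np.repeat(plane[:, :, None], len(zs), axis=2)
    return PotentialGrid(
        origin=np.array([-hs, -hs, z_range[0]]),
        spacing=np.array([spacing, spacing, spacing]),
        shape=values.shape,
        values=values,
    )


def write_complex_files(outdir, config: GeneratorConfig | None = None) -> dict:
    """Generate a complex and write DMS + OpenDX files exercising the readers.

    Writes A.dms, B.dms, A.dx, B.dx and annotations.tsv under ``outdir``.
    The potential grids replicate each side's planar field along z (B's
    including the sign flips), so nearest-node sampling approximately
    reproduces the per-point potentials.  Returns the ground-truth dict
    plus the written paths.
    """
    config = config or GeneratorConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    psurf_A, psurf_B, gt = gen_complex(config)
    phi = gt["potential_field"]
    flip = gt["flip_field"]
    threshold = gt["flip_threshold"]

    def phi_B_field(xy):
        base = phi(xy)
        flipped = flip(xy) >= threshold
        return np.where(flipped, base, -base)

    zlo = float(min(psurf_A.surface.points[:, 2].min(), psurf_B.surface.points[:, 2].min())) - 1.5
    zhi = float(max(psurf_A.surface.points[:, 2].max(), psurf_B.surface.points[:, 2].max())) + 1.5
    paths = {
        "dms_A": outdir / "A.dms",
        "dms_B": outdir / "B.dms",
        "dx_A": outdir / "A.dx",
        "dx_B": outdir / "B.dx",
        "annotations": outdir / "annotations.tsv",
    }
    write_dms(psurf_A.surface, paths["dms_A"])
    write_dms(psurf_B.surface, paths["dms_B"])
    write_dx(_field_grid(config, phi, (zlo, zhi)), paths["dx_A"])
    write_dx(_field_grid(config, phi_B_field, (zlo, zhi)), paths["dx_B"])
    with open(paths["annotations"], "w") as fh:
        fh.write("pdb_id\tpH\tKd\tdimer_class\tstructural_class\n")
        fh.write(f"synthetic-{config.seed}\t7.0\t1e-08\tnIBR-het\tHH\n")
    gt["paths"] = paths
    return gt
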