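"""2D Zernike expansion of projected surface patches.

A real function f(r, psi) on the unit disk is expanded in the Zernike basis

    f(r, psi) = sum_{n'} sum_{m} c_{n'm} Z_{n'm}(r, psi),
    Z_{n'm}(r, psi) = R_{n'm}(r) e^{i m psi},

with the radial polynomial

    R_{n'm}(r) = sum_k (-1)^k (n'-k)! / [k! ((n'+m)/2-k)! ((n'-m)/2-k)!]
                 * r^{n'-2k},        k = 0 .. (n'-m)/2,

defined for 0 <= m <= n' with n'-m even.  The basis is orthogonal,
<Z_{n'm}|Z_{n''m'}> = pi/(n'+1) delta delta, and the moduli z_{n'm} =
|c_{n'm}| are invariant under in-plane rotation of f, which makes them a
superposition-free descriptor of a surface patch: two patches are compared
by the Euclidean distance between their descriptor vectors.

Radial coefficients are multinomial integers ((n'-k)! / (k! a! b!) with
k + a + b = n' - k), computed exactly in Python integers, so the endpoint
identity R_{n'm}(1) = 1 holds to machine precision at any order.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import factorial, pi

import numpy as np

from .patch_projection import ProjectionMatrix

__all__ = [
    "ZernikeIndex",
    "ZernikeExpansion",
    "ZernikeDescriptor",
    "zernike_indices",
    "radial_poly",
    "zernike_poly",
    "expand",
    "expand_function",
    "expand_polar",
    "invariants",
    "rotate_expansion",
    "reconstruct",
    "descriptor_distance",
    "disk_inner_product",
]


class InvalidIndexError(ValueError):
    """Raised for (n', m) pairs violating 0 <= m <= n', n'-m even."""


@dataclass(frozen=True)
class ZernikeIndex:
    """Radial order n' and azimuthal order m, with n'-m even."""

    n_prime: int
    m: int

    def __post_init__(self) -> None:
        n, m = self.n_prime, self.m
        if n < 0 or m < 0 or m > n or (n - m) % 2 != 0:
            raise InvalidIndexError(
                f"invalid Zernike index (n'={n}, m={m}): need 0 <= m <= n' "
                "and n'-m even"
            )


def zernike_indices(order: int) -> list[tuple[int, int]]:
    """All valid (n', m) pairs with n' <= order, in lexicographic order.

    At order 20 there are exactly 121 pairs.
    """
    return [(n, m) for n in range(order + 1) for m in range(n % 2, n + 1, 2)]


@lru_cache(maxsize=None)
def _radial_coeffs(n: int, m: int) -> tuple[tuple[int, int], ...]:
    """Exact integer coefficients [(power, coeff), ...] of R_{n'm}."""
    ZernikeIndex(n, m)
    out = []
    for k in range((n - m) // 2 + 1):
        c = (-1) ** k * factorial(n - k) // (
            factorial(k)
            * factorial((n + m) // 2 - k)
            * factorial((n - m) // 2 - k)
        )
        out.append((n - 2 * k, c))
    return tuple(out)


def radial_poly(n_prime: int, m: int, r):
    """Evaluate the radial polynomial R_{n'm} at radii ``r`` in [0, 1]."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    for power, coeff in _radial_coeffs(n_prime, m):
        out += float(coeff) * r**power
    return out


def zernike_poly(n_prime: int, m: int, r, psi):
    """Complex Zernike polynomial Z_{n'm}(r, psi) = R_{n'm}(r) e^{i m psi}."""
    psi = np.asarray(psi, dtype=float)
    return radial_poly(n_prime, m, r) * np.exp(1j * m * psi)


@dataclass
class ZernikeExpansion:
    """Complex expansion coefficients c_{n'm} for all n' <= order."""

    order: int
    coefficients: np.ndarray  # complex, aligned with zernike_indices(order)
    disk_scale: float = 1.0  # physical radius (Angstrom) mapped to r = 1

    def __post_init__(self) -> None:
        expected = len(zernike_indices(self.order))
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        if self.coefficients.shape != (expected,):
            raise ValueError(
                f"expected {expected} coefficients at order {self.order}, "
                f"got shape {self.coefficients.shape}"
            )


@dataclass
class ZernikeDescriptor:
    """Rotation-invariant descriptor: moduli |c_{n'm}| in index order."""

    order: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = len(zernike_indices(self.order))
        if self.values.shape != (expected,):
            raise ValueError(
                f"descriptor at order {self.order} must have {expected} "
                f"entries, got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("descriptor moduli must be non-negative")

    def __len__(self) -> int:
        return len(self.values)


def _coefficients_from_samples(
    r: np.ndarray, psi: np.ndarray, f: np.ndarray, w: np.ndarray, order: int
) -> np.ndarray:
    """Discretized projection c_{n'm} = (n'+1)/pi * sum w Z* f."""
    fw = f * w
    coeffs = np.empty(len(zernike_indices(order)), dtype=complex)
    for i, (n, m) in enumerate(zernike_indices(order)):
        zs = np.conj(zernike_poly(n, m, r, psi))
        coeffs[i] = (n + 1) / pi * np.sum(zs * fw)
    return coeffs


def expand(matrix: ProjectionMatrix, order: int = 20) -> ZernikeExpansion:
    """Expand a projection matrix in the Zernike basis.

    The matrix value is treated as piecewise constant over its pixel.
    Pixels fully inside the unit disk enter as midpoint terms with weight
    equal to the pixel area; pixels straddling the rim are subdivided so
    only their area inside the disk contributes (an all-or-nothing rim
    rule couples the field's rim values to the grid orientation and
    spoils rotation invariance at high order).  Masked-out pixels
    contribute zero.
    """
    grid = np.asarray(matrix.grid, dtype=float)
    mask = np.asarray(matrix.mask, dtype=bool)
    g = grid.shape[0]
    interior, rim_idx, rim_nodes = _pixel_disk_geometry(g)
    keep_int = mask & interior
    rs, psis, fs, ws = [], [], [], []
    if np.any(keep_int):
        c = (np.arange(g) + 0.5) * (2.0 / g) - 1.0
        X, Y = np.meshgrid(c, c, indexing="ij")
        rs.append(np.hypot(X[keep_int], Y[keep_int]))
        psis.append(np.arctan2(Y[keep_int], X[keep_int]))
        fs.append(grid[keep_int])
        ws.append(np.full(int(keep_int.sum()), (2.0 / g) ** 2))
    for (i, j), (rx, ry, wsub) in zip(rim_idx, rim_nodes):
        if not mask[i, j]:
            continue
        rs.append(np.hypot(rx, ry))
        psis.append(np.arctan2(ry, rx))
        fs.append(np.full(len(rx), grid[i, j]))
        ws.append(wsub)
    if not rs:
        raise ValueError("cannot expand: all pixels masked out or outside disk")
    coeffs = _coefficients_from_samples(
        np.concatenate(rs), np.concatenate(psis), np.concatenate(fs),
        np.concatenate(ws), order,
    )
    return ZernikeExpansion(order, coeffs, disk_scale=matrix.disk_scale)


@lru_cache(maxsize=8)
def _pixel_disk_geometry(g: int, sub: int = 8):
    """Interior mask plus subsampled in-disk nodes for rim pixels."""
    h = 2.0 / g
    c = (np.arange(g) + 0.5) * h - 1.0
    X, Y = np.meshgrid(c, c, indexing="ij")
    far = np.hypot(np.abs(X) + h / 2, np.abs(Y) + h / 2)
    near = np.hypot(
        np.maximum(np.abs(X) - h / 2, 0.0), np.maximum(np.abs(Y) - h / 2, 0.0)
    )
    interior = far <= 1.0
    rim = (near < 1.0) & ~interior
    off = ((np.arange(sub) + 0.5) / sub - 0.5) * h
    OX, OY = np.meshgrid(off, off, indexing="ij")
    rim_idx, rim_nodes = [], []
    for i, j in zip(*np.nonzero(rim)):
        rx = X[i, j] + OX.ravel()
        ry = Y[i, j] + OY.ravel()
        inside = rx**2 + ry**2 <= 1.0
        if not np.any(inside):
            continue
        rim_idx.append((int(i), int(j)))
        rim_nodes.append(
            (rx[inside], ry[inside], np.full(int(inside.sum()), h * h / sub**2))
        )
    return interior, tuple(rim_idx), tuple(rim_nodes)


def expand_function(func, order: int = 20, n_pixels: int = 201) -> ZernikeExpansion:
    """Expand an analytic field func(r, psi) sampled at pixel centers.

    Convenience for validation against closed-form coefficients; same
    midpoint rule as :func:`expand`.
    """
    c = (np.arange(n_pixels) + 0.5) * (2.0 / n_pixels) - 1.0
    X, Y = np.meshgrid(c, c, indexing="ij")
    r = np.hypot(X, Y)
    keep = r <= 1.0
    psi = np.arctan2(Y[keep], X[keep])
    rr = r[keep]
    f = np.asarray(func(rr, psi), dtype=float)
    w = np.full(keep.sum(), (2.0 / n_pixels) ** 2)
    return ZernikeExpansion(order, _coefficients_from_samples(rr, psi, f, w, order))


def expand_polar(func, order: int = 20, n_r: int = 64, n_psi: int = 256) -> ZernikeExpansion:
    """Expand an analytic field with a polar Gauss-Legendre x uniform rule.

    The angular trapezoid rule is spectrally exact for band-limited fields,
    so an in-plane rotation of ``func`` shifts every coefficient by a pure
    phase and leaves the moduli unchanged to machine precision.
    """
    x, wx = np.polynomial.legendre.leggauss(n_r)
    r = 0.5 * (x + 1.0)  # map [-1,1] -> [0,1]
    wr = 0.5 * wx * r  # Jacobian r dr
    psi = np.arange(n_psi) * (2.0 * pi / n_psi)
    wpsi = 2.0 * pi / n_psi
    R, PSI = np.meshgrid(r, psi, indexing="ij")
    W = np.broadcast_to((wr * wpsi)[:, None], R.shape)
    f = np.asarray(func(R.ravel(), PSI.ravel()), dtype=float)
    coeffs = _coefficients_from_samples(R.ravel(), PSI.ravel(), f, W.ravel(), order)
    return ZernikeExpansion(order, coeffs)


def invariants(expansion: ZernikeExpansion) -> ZernikeDescriptor:
    """Rotation-invariant moduli z_{n'm} = |c_{n'm}|."""
    return ZernikeDescriptor(expansion.order, np.abs(expansion.coefficients))


def rotate_expansion(expansion: ZernikeExpansion, alpha: float) -> ZernikeExpansion:
    """Coefficients of the field rotated in-plane by ``alpha`` radians.

    f(r, psi + alpha) has coefficients c_{n'm} e^{i m alpha}; the moduli —
    hence the descriptor — are exactly unchanged.
    """
    ms = np.array([m for _, m in zernike_indices(expansion.order)])
    return ZernikeExpansion(
        expansion.order,
        expansion.coefficients * np.exp(1j * ms * alpha),
        disk_scale=expansion.disk_scale,
    )


def reconstruct(expansion: ZernikeExpansion, grid_shape: tuple[int, int]) -> np.ndarray:
    """Reconstruct the (real) field on a pixel grid from the truncated sum.

    Uses the real-function convention f = sum_{m>=0} w_m Re(c_{n'm} Z_{n'm})
    with w_0 = 1, w_{m>0} = 2 (conjugate-symmetric completion).  Pixels
    outside the unit disk are NaN.
    """
    gx, gy = grid_shape
    cx = (np.arange(gx) + 0.5) * (2.0 / gx) - 1.0
    cy = (np.arange(gy) + 0.5) * (2.0 / gy) - 1.0
    X, Y = np.meshgrid(cx, cy, indexing="ij")
    r = np.hypot(X, Y)
    psi = np.arctan2(Y, X)
    inside = r <= 1.0
    out = np.full(grid_shape, np.nan)
    acc = np.zeros(inside.sum())
    for (n, m), c in zip(zernike_indices(expansion.order), expansion.coefficients):
        w = 1.0 if m == 0 else 2.0
        acc += w * np.real(c * zernike_poly(n, m, r[inside], psi[inside]))
    out[inside] = acc
    return out


def descriptor_distance(d1: ZernikeDescriptor, d2: ZernikeDescriptor) -> float:
    """Euclidean distance between two invariant descriptors."""
    if d1.order != d2.order:
        raise ValueError(
            f"descriptor order mismatch: {d1.order} != {d2.order}"
        )
    return float(np.linalg.norm(d1.values - d2.values))


def disk_inner_product(
    idx1: tuple[int, int], idx2: tuple[int, int], n_pixels: int = 201
) -> complex:
    """Numeric <Z_{n'm}|Z_{n''m'}> on an ``n_pixels`` square disk grid.

    Exact value is pi/(n'+1) * delta_{n'n''} delta_{mm'}.  Interior pixels
    use a composite 2x2 Gauss rule and rim pixels a 16x16 midpoint
    subdivision, which keeps the quadrature error well below 1e-3 for
    orders up to ~10 (plain pixel-center midpoint does not, because of the
    steep high-order integrands near r = 1).
    """
    r, psi, w = _disk_quadrature(n_pixels)
    z1 = zernike_poly(*idx1, r, psi)
    z2 = zernike_poly(*idx2, r, psi)
    return complex(np.sum(np.conj(z1) * z2 * w))


@lru_cache(maxsize=4)
def _disk_quadrature(n_pixels: int, rim_sub: int = 16):
    h = 2.0 / n_pixels
    c = (np.arange(n_pixels) + 0.5) * h - 1.0
    X, Y = np.meshgrid(c, c, indexing="ij")
    far = np.hypot(np.abs(X) + h / 2, np.abs(Y) + h / 2)
    near = np.hypot(
        np.maximum(np.abs(X) - h / 2, 0.0), np.maximum(np.abs(Y) - h / 2, 0.0)
    )
    interior = far <= 1.0
    rim = (near < 1.0) & ~interior
    xs, ys, ws = [], [], []
    g = h / (2.0 * np.sqrt(3.0))
    for ox, oy in ((-g, -g), (-g, g), (g, -g), (g, g)):
        xs.append(X[interior] + ox)
        ys.append(Y[interior] + oy)
        ws.append(np.full(int(interior.sum()), h * h / 4.0))
    off = ((np.arange(rim_sub) + 0.5) / rim_sub - 0.5) * h
    OX, OY = np.meshgrid(off, off, indexing="ij")
    rx = X[rim][:, None] + OX.ravel()[None, :]
    ry = Y[rim][:, None] + OY.ravel()[None, :]
    rin = rx**2 + ry**2 <= 1.0
    xs.append(rx[rin])
    ys.append(ry[rin])
    ws.append(np.full(int(rin.sum()), h * h / rim_sub**2))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    w = np.concatenate(ws)
    return np.hypot(x, y), np.arctan2(y, x), w
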