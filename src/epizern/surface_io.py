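"""Readers for molecular surfaces (DMS), potential grids (OpenDX) and PDB.

The pipeline consumes three standard artefacts: a solvent-accessible
surface sampled as an oriented point cloud (the DMS program's output
dialect, nominally 5 points per square Angstrom with outward unit normals
from ``dms -n``), a scalar electrostatic-potential grid as written by
Poisson-Boltzmann solvers such as APBS (OpenDX "regular positions, regular
connections"), and the atomic structure itself for residue bookkeeping.
Potential values are carried opaquely in the solver's output units
(k_BT/e for APBS); no unit conversion is applied anywhere downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "MolecularSurface",
    "PotentialGrid",
    "PotentialSurface",
    "Structure",
    "read_dms",
    "write_dms",
    "read_dx",
    "write_dx",
    "read_pdb",
    "sample_potential",
]


class SurfaceFormatError(ValueError):
    """Malformed surface / grid / structure input."""


RESIDUE_TAG_DTYPE = np.dtype(
    [("chain", "U4"), ("resnum", "U8"), ("resname", "U4")]
)


@dataclass
class MolecularSurface:
    """Oriented point cloud sampling a solvent-accessible surface."""

    points: np.ndarray  # (n, 3) Angstrom
    normals: np.ndarray  # (n, 3) outward unit vectors
    residue_tags: np.ndarray  # structured (chain, resnum, resname)
    density: float = 5.0  # nominal points per Angstrom^2

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
        self.residue_tags = np.asarray(self.residue_tags, dtype=RESIDUE_TAG_DTYPE)
        if len(self.points) != len(self.normals) or len(self.points) != len(
            self.residue_tags
        ):
            raise ValueError("points, normals and residue_tags must align")
        if self.density <= 0:
            raise ValueError("density must be positive")
        norms = np.linalg.norm(self.normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("normals must be unit vectors (renormalize on read)")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PotentialGrid:
    """Regular scalar grid of electrostatic potential (solver units)."""

    origin: np.ndarray  # (3,) Angstrom
    spacing: np.ndarray  # (3,) Angstrom, positive
    shape: tuple[int, int, int]
    values: np.ndarray  # (nx, ny, nz); file order is z-fastest

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.shape = tuple(int(s) for s in self.shape)
        if np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be positive")
        if self.values.shape != self.shape:
            raise SurfaceFormatError(
                f"value block shape {self.values.shape} does not match "
                f"declared extents {self.shape}"
            )


@dataclass
class PotentialSurface:
    """Molecular surface with one potential value per point."""

    surface: MolecularSurface
    potential: np.ndarray

    def __post_init__(self) -> None:
        self.potential = np.asarray(self.potential, dtype=float)
        if len(self.potential) != len(self.surface):
            raise ValueError("one potential value per surface point required")
        if not np.all(np.isfinite(self.potential)):
            raise ValueError("potential values must be finite")


@dataclass
class Structure:
    """Atomic coordinates with residue bookkeeping.

    ``atoms`` columns: chain, resnum (str, insertion code appended),
    resname, atom, x, y, z.
    """

    atoms: pd.DataFrame
    chains: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)


# ---------------------------------------------------------------------------
# DMS surface dialect
# ---------------------------------------------------------------------------
# Records look like
#   SER A12  OG   12.100   4.310   9.200 SR0  0.406  0.00  0.00  1.00
# i.e. resname, chain+resnum, atom name, x y z, record type, and for
# surface points the per-point area followed by the unit normal.  Atom
# records (type starting with 'A') carry no normal and are skipped: only
# surface points sample the surface.  Whitespace is free-form.

_CHAIN_RE = re.compile(r"^([A-Za-z]*)(-?\d+\w*)$")


def _split_resid(token: str) -> tuple[str, str]:
    m = _CHAIN_RE.match(token)
    if m and m.group(1):
        return m.group(1), m.group(2)
    return "A", token


def read_dms(path, density: float = 5.0) -> MolecularSurface:
    """Read a DMS surface file, keeping only surface-point records.

    Normals are renormalized to unit length.  Surface points without a
    normal triple are an error: the surface must be regenerated with
    normals enabled (``dms -n``).
    """
    points, normals, tags = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise SurfaceFormatError(
                    f"{path}:{lineno}: expected at least 7 fields, got {len(parts)}"
                )
            resname, resid, _atom = parts[0], parts[1], parts[2]
            rectype = parts[6]
            if rectype.startswith("A"):
                continue  # atom record, not a surface point
            if not rectype.startswith("S"):
                raise SurfaceFormatError(
                    f"{path}:{lineno}: unknown record type {rectype!r}"
                )
            if len(parts) < 11:
                raise SurfaceFormatError(
                    f"{path}:{lineno}: surface point lacks a normal triple; "
                    "regenerate the surface with normals enabled (dms -n)"
                )
            try:
                xyz = [float(v) for v in parts[3:6]]
                nvec = [float(v) for v in parts[8:11]]
            except ValueError as exc:
                raise SurfaceFormatError(f"{path}:{lineno}: {exc}") from exc
            norm = float(np.linalg.norm(nvec))
            if norm < 1e-9:
                raise SurfaceFormatError(
                    f"{path}:{lineno}: zero-length normal; regenerate with dms -n"
                )
            chain, resnum = _split_resid(resid)
            points.append(xyz)
            normals.append([v / norm for v in nvec])
            tags.append((chain, resnum, resname))
    if not points:
        raise SurfaceFormatError(f"{path}: no surface-point records found")
    return MolecularSurface(
        points=np.array(points),
        normals=np.array(normals),
        residue_tags=np.array(tags, dtype=RESIDUE_TAG_DTYPE),
        density=density,
    )


def write_dms(surface: MolecularSurface, path) -> None:
    """Write a surface in the DMS surface-point dialect (round-trippable)."""
    with open(path, "w") as fh:
        for p, n, t in zip(surface.points, surface.normals, surface.residue_tags):
            fh.write(
                f"{t['resname']:<4s} {t['chain']}{t['resnum']:<6s} P "
                f"{p[0]:12.6f} {p[1]:12.6f} {p[2]:12.6f} SR0 "
                f"{1.0 / surface.density:8.4f} "
                f"{n[0]:10.6f} {n[1]:10.6f} {n[2]:10.6f}\n"
            )


# ---------------------------------------------------------------------------
# OpenDX scalar grids
# ---------------------------------------------------------------------------


def read_dx(path) -> PotentialGrid:
    """Read an OpenDX regular scalar grid (APBS potential output).

    Delegates parsing to gridData (GridDataFormats); only the "regular
    positions, regular connections" dialect is supported, and the value
    count must match the declared extents.
    """
    from gridData import Grid

    _check_dx_header(path)
    try:
        g = Grid(str(path))
    except Exception as exc:  # noqa: BLE001 - wrap any parser failure
        raise SurfaceFormatError(
            f"{path}: not a readable regular OpenDX scalar grid ({exc})"
        ) from exc
    delta = np.asarray(g.delta, dtype=float)
    if delta.ndim == 2:
        off = delta - np.diag(np.diag(delta))
        if np.any(np.abs(off) > 1e-12):
            raise SurfaceFormatError(f"{path}: non-axis-aligned grid is unsupported")
        delta = np.diag(delta)
    values = np.asarray(g.grid, dtype=float)
    return PotentialGrid(
        origin=np.asarray(g.origin, dtype=float),
        spacing=delta,
        shape=values.shape,
        values=values,
    )


def _check_dx_header(path) -> None:
    """Integrity checks gridData performs silently: dialect and counts."""
    counts = None
    items = None
    with open(path) as fh:
        for _ in range(200):
            line = fh.readline()
            if not line:
                break
            if "gridpositions counts" in line:
                counts = [int(t) for t in line.split()[-3:]]
            elif line.startswith("object 3") and " items " in line:
                items = int(line.split("items")[1].split()[0])
            if counts is not None and items is not None:
                break
    if counts is None:
        raise SurfaceFormatError(
            f"{path}: not a 'regular positions, regular connections' OpenDX grid"
        )
    if items is not None and items != counts[0] * counts[1] * counts[2]:
        raise SurfaceFormatError(
            f"{path}: declared extents {tuple(counts)} imply "
            f"{counts[0] * counts[1] * counts[2]} values but the data array "
            f"declares {items}"
        )


def write_dx(grid: PotentialGrid, path) -> None:
    """Write a grid as OpenDX (z-fastest value order)."""
    from gridData import Grid

    g = Grid(grid.values, origin=grid.origin, delta=grid.spacing)
    g.export(str(path), file_format="dx")


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

_WATERS = {"HOH", "WAT", "DOD"}


def read_pdb(path) -> Structure:
    """Read ATOM/HETATM records for residue bookkeeping.

    Alternate locations keep only blank/'A'; waters and hydrogens are
    dropped (they play no role in residue-level interface analyses).
    Insertion codes are appended to the residue number so they stay part
    of the residue identity.
    """
    import gemmi

    st = gemmi.read_pdb(str(path))
    rows = []
    chains: list[str] = []
    for model in st:
        for chain in model:
            for res in chain:
                if res.name in _WATERS:
                    continue
                for atom in res:
                    if atom.element.is_hydrogen:
                        continue
                    if atom.altloc not in ("\0", "", "A"):
                        continue
                    icode = res.seqid.icode.strip()
                    rows.append(
                        (
                            chain.name,
                            f"{res.seqid.num}{icode}",
                            res.name,
                            atom.name,
                            atom.pos.x,
                            atom.pos.y,
                            atom.pos.z,
                        )
                    )
                if chain.name not in chains:
                    chains.append(chain.name)
        break  # first model only
    if not rows:
        raise SurfaceFormatError(f"{path}: no ATOM/HETATM records")
    atoms = pd.DataFrame(
        rows, columns=["chain", "resnum", "resname", "atom", "x", "y", "z"]
    )
    return Structure(atoms=atoms, chains=chains)


# ---------------------------------------------------------------------------
# Potential sampling
# ---------------------------------------------------------------------------


def sample_potential(
    grid: PotentialGrid,
    surface: MolecularSurface,
    method: str = "nearest",
) -> PotentialSurface:
    """Assign each surface point the potential of its grid cell.

    Default is the nearest grid node (the cell "corresponding to" the
    point); ``method='linear'`` switches to trilinear interpolation.
    Points outside the grid bounding box are an error listing the
    offending indices.
    """
    pts = surface.points
    rel = (pts - grid.origin) / grid.spacing
    upper = np.array(grid.shape) - 1
    outside = np.any((rel < -0.5) | (rel > upper + 0.5), axis=1)
    if np.any(outside):
        idx = np.flatnonzero(outside)
        shown = ", ".join(map(str, idx[:10]))
        more = "" if len(idx) <= 10 else f" (+{len(idx) - 10} more)"
        raise ValueError(
            f"{len(idx)} surface points fall outside the potential grid: "
            f"indices {shown}{more}"
        )
    if method == "nearest":
        ijk = np.clip(np.rint(rel).astype(int), 0, upper)
        vals = grid.values[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
    elif method == "linear":
        from scipy.interpolate import RegularGridInterpolator

        axes = [
            grid.origin[d] + grid.spacing[d] * np.arange(grid.shape[d])
            for d in range(3)
        ]
        interp = RegularGridInterpolator(
            axes, grid.values, bounds_error=False, fill_value=None
        )
        vals = interp(pts)
    else:
        raise ValueError(f"unknown sampling method {method!r}")
    return PotentialSurface(surface=surface, potential=np.asarray(vals, dtype=float))
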