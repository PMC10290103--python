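"""Interfaces, surface patches, decoys and complex classification.

The interacting region of a complex is the set of surface points of one
partner closer than 6 Angstrom to the partner's surface.  Patches are
spherical selections (default radius 9 Angstrom) centred on a surface
point: the point nearest the interface centroid for binding patches, a
uniformly drawn point for random decoys.  Complexes are classified by the
residue overlap of the two binding regions (IBR / SBR / nIBR homodimers,
heterodimers) and by the prevailing secondary structure of each partner
(HH / SS / SH).  Surface residues are those with relative solvent
accessibility (SASA / max SASA) above 0.25; the theoretical maximum SASA
per residue is the Tien et al. (2013) table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.spatial import cKDTree

from .surface_io import MolecularSurface

__all__ = [
    "Patch",
    "InterfaceAnnotation",
    "ComplexRecord",
    "ResidueAccessibility",
    "MAX_SASA",
    "SparsePatchError",
    "find_interface",
    "patch_center",
    "extract_patch",
    "random_patch",
    "surface_residues",
    "classify_dimer",
    "classify_structural",
]

DEFAULT_INTERFACE_CUTOFF = 6.0
DEFAULT_PATCH_RADIUS = 9.0
DEFAULT_MIN_PATCH_POINTS = 20
DEFAULT_RSA_THRESHOLD = 0.25

# Theoretical maximum solvent-accessible surface areas (Angstrom^2),
# Tien et al. 2013, used as the RSA denominator.
MAX_SASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

DIMER_CLASSES = ("IBR-hom", "SBR-hom", "nIBR-hom", "nIBR-het")
STRUCTURAL_CLASSES = ("HH", "SS", "SH")


class SparsePatchError(ValueError):
    """Patch contains fewer points than the configured minimum."""


@dataclass
class Patch:
    """Spherical surface selection: indices within ``radius`` of ``center``."""

    surface_ref: str
    point_indices: np.ndarray
    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.point_indices = np.asarray(self.point_indices, dtype=int)
        self.center = np.asarray(self.center, dtype=float)

    def __len__(self) -> int:
        return len(self.point_indices)


@dataclass
class InterfaceAnnotation:
    """Per-point interface flags and derived residue sets for both partners."""

    mask_A: np.ndarray
    mask_B: np.ndarray
    residues_A: set
    residues_B: set
    cutoff: float = DEFAULT_INTERFACE_CUTOFF


@dataclass
class ComplexRecord:
    """A complex with its annotations (pH, affinity, classifications)."""

    pdb_id: str
    pH: Optional[float] = None
    Kd: Optional[float] = None
    Ba: Optional[float] = None
    dimer_class: Optional[str] = None
    structural_class: Optional[str] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.Kd is not None:
            if self.Kd <= 0:
                raise ValueError("Kd must be positive")
            ba = float(np.log10(self.Kd))
            if self.Ba is None:
                self.Ba = ba
            elif abs(self.Ba - ba) > 1e-6:
                raise ValueError(
                    f"inconsistent affinity: Ba={self.Ba} but log10(Kd)={ba:.6f}"
                )
        if self.dimer_class is not None and self.dimer_class not in DIMER_CLASSES:
            raise ValueError(f"unknown dimer class {self.dimer_class!r}")
        if (
            self.structural_class is not None
            and self.structural_class not in STRUCTURAL_CLASSES
        ):
            raise ValueError(f"unknown structural class {self.structural_class!r}")


@dataclass
class ResidueAccessibility:
    """Per-residue SASA with the tabulated maximum and their ratio."""

    residue: tuple  # (chain, resnum, resname) or any hashable id ending in resname
    sasa: float
    max_sasa: float
    rsa: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.max_sasa <= 0:
            raise ValueError("max_sasa must be positive")
        if self.rsa is None:
            self.rsa = self.sasa / self.max_sasa
        if self.rsa < 0:
            raise ValueError("rsa must be non-negative")


def _residues_from_mask(surface: MolecularSurface, mask: np.ndarray) -> set:
    tags = surface.residue_tags[mask]
    return {(t["chain"], t["resnum"], t["resname"]) for t in tags}


def find_interface(
    surf_A: MolecularSurface,
    surf_B: MolecularSurface,
    cutoff: float = DEFAULT_INTERFACE_CUTOFF,
) -> InterfaceAnnotation:
    """Flag points of each surface closer than ``cutoff`` to the partner.

    Symmetric by construction; an empty interface is returned as empty
    masks, not an error.
    """
    if len(surf_A) == 0 or len(surf_B) == 0:
        raise ValueError("both surfaces must be non-empty")
    tree_A = cKDTree(surf_A.points)
    tree_B = cKDTree(surf_B.points)
    dist_A, _ = tree_B.query(surf_A.points, k=1)
    dist_B, _ = tree_A.query(surf_B.points, k=1)
    mask_A = dist_A < cutoff
    mask_B = dist_B < cutoff
    return InterfaceAnnotation(
        mask_A=mask_A,
        mask_B=mask_B,
        residues_A=_residues_from_mask(surf_A, mask_A),
        residues_B=_residues_from_mask(surf_B, mask_B),
        cutoff=cutoff,
    )


def patch_center(
    annotation: InterfaceAnnotation, surface: MolecularSurface, side: str = "A"
) -> np.ndarray:
    """Surface point nearest the geometric centre of the interface.

    The centroid of the flagged points is generally off-surface, so the
    flagged point closest to it is returned; ties break to the lowest
    point index.
    """
    mask = annotation.mask_A if side == "A" else annotation.mask_B
    if not np.any(mask):
        raise ValueError(f"no interface points flagged on side {side}")
    flagged = surface.points[mask]
    centroid = flagged.mean(axis=0)
    d = np.linalg.norm(flagged - centroid, axis=1)
    return flagged[int(np.argmin(d))].copy()


def extract_patch(
    surface: MolecularSurface,
    center: np.ndarray,
    radius: float = DEFAULT_PATCH_RADIUS,
    min_points: int = DEFAULT_MIN_PATCH_POINTS,
    surface_ref: str = "",
) -> Patch:
    """All surface points within ``radius`` of ``center`` (inclusive)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    center = np.asarray(center, dtype=float)
    d = np.linalg.norm(surface.points - center, axis=1)
    idx = np.flatnonzero(d <= radius)
    if len(idx) < min_points:
        raise SparsePatchError(
            f"patch has {len(idx)} points, fewer than the minimum {min_points}"
        )
    return Patch(surface_ref=surface_ref, point_indices=idx, center=center, radius=radius)


def random_patch(
    surface: MolecularSurface,
    radius: float = DEFAULT_PATCH_RADIUS,
    rng=None,
    min_points: int = DEFAULT_MIN_PATCH_POINTS,
    max_retries: int = 50,
    surface_ref: str = "",
) -> Patch:
    """Patch around a uniformly drawn surface point; resamples sparse draws."""
    rng = np.random.default_rng(rng)
    last_err: Optional[Exception] = None
    for _ in range(max_retries):
        i = int(rng.integers(len(surface)))
        try:
            return extract_patch(
                surface,
                surface.points[i],
                radius=radius,
                min_points=min_points,
                surface_ref=surface_ref,
            )
        except SparsePatchError as exc:
            last_err = exc
    raise SparsePatchError(
        f"no patch with >= {min_points} points found in {max_retries} draws"
    ) from last_err


def surface_residues(
    accessibilities: Iterable[ResidueAccessibility],
    threshold: float = DEFAULT_RSA_THRESHOLD,
) -> set:
    """Residues with relative solvent accessibility strictly above threshold."""
    return {a.residue for a in accessibilities if a.rsa > threshold}


def rsa_from_sasa(residue: tuple, sasa: float) -> ResidueAccessibility:
    """Build a ResidueAccessibility using the embedded max-SASA table.

    ``residue`` must end with the three-letter residue name.
    """
    resname = residue[-1]
    if resname not in MAX_SASA:
        raise KeyError(f"no max-SASA reference for residue {resname!r}")
    return ResidueAccessibility(residue=residue, sasa=sasa, max_sasa=MAX_SASA[resname])


def classify_dimer(residues_A: set, residues_B: set, is_heterodimer: bool = False) -> str:
    """Dimer class from the overlap of the two binding-region residue sets.

    Homodimer sets must be expressed in a shared numbering frame.  The
    overlap fraction f = |A n B| / min(|A|, |B|) maps to IBR-hom
    (f >= 0.7), SBR-hom (0.3 <= f < 0.7) or nIBR-hom (f < 0.3);
    heterodimers are nIBR-het regardless.
    """
    if is_heterodimer:
        return "nIBR-het"
    if not residues_A or not residues_B:
        raise ValueError("binding-region residue sets must be non-empty")
    f = len(residues_A & residues_B) / min(len(residues_A), len(residues_B))
    if f >= 0.7:
        return "IBR-hom"
    if f >= 0.3:
        return "SBR-hom"
    return "nIBR-hom"


def _prevailing(labels: Iterable[str]) -> str:
    counts = {"H": 0, "S": 0}
    for lab in labels:
        if lab in counts:
            counts[lab] += 1
    if counts["H"] == 0 and counts["S"] == 0:
        raise ValueError("chain has no helix or strand residues; unclassifiable")
    # tie -> S (documented, deterministic)
    return "H" if counts["H"] > counts["S"] else "S"


def classify_structural(ss_A: Iterable[str], ss_B: Iterable[str]) -> str:
    """HH / SS / SH from per-residue secondary-structure labels (H, S, other)."""
    a, b = _prevailing(ss_A), _prevailing(ss_B)
    if a == b:
        return a + b
    return "SH"
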