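"""Amino-acid composition and charge statistics at interfaces.

Formal charges at physiological pH (ASP/GLU -1, LYS/ARG +1, HIS and all
others 0) drive three analyses: the sign of the product of the two
partners' net charges (over all residues and over interface residues
only — for a homodimer the total product is a square, hence never
negative), relative amino-acid abundances over the whole chain / the
solvent-exposed residues / the interacting residues, and the percentage
of interface residues of each charge class that face a partner residue of
each charge class within a given radius.  The charge table is
user-overridable (e.g. HIS +1 below pH 6).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .surface_io import Structure

__all__ = [
    "AMINO_ACIDS",
    "DEFAULT_CHARGES",
    "residue_charge",
    "charge_products",
    "composition_profile",
    "cross_interface_neighbor_stats",
    "residue_representative_points",
]

AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

DEFAULT_CHARGES: dict[str, int] = {aa: 0 for aa in AMINO_ACIDS}
DEFAULT_CHARGES.update({"ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1})

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def residue_charge(name: str, table: Optional[Mapping[str, int]] = None) -> int:
    """Formal charge (integer e) of a residue by table lookup."""
    table = DEFAULT_CHARGES if table is None else table
    if name not in table:
        raise KeyError(f"unknown residue {name!r}: not in charge table")
    return int(table[name])


def _net_charge(resnames: Iterable[str], table: Mapping[str, int]) -> int:
    return sum(residue_charge(r, table) for r in resnames)


def charge_products(
    residues_A: Iterable[str],
    residues_B: Iterable[str],
    interface_A: Iterable[str],
    interface_B: Iterable[str],
    table: Optional[Mapping[str, int]] = None,
) -> tuple[int, int]:
    """Signs of the products of the partners' net charges.

    Returns (total_sign, interface_sign) where each sign is -1, 0 or +1:
    the sign of (sum of charges of A) x (sum of charges of B) over all
    residues and over interface residues respectively.  A zero net charge
    on either side gives sign 0.
    """
    table = DEFAULT_CHARGES if table is None else table
    total = _net_charge(residues_A, table) * _net_charge(residues_B, table)
    iface = _net_charge(interface_A, table) * _net_charge(interface_B, table)
    return int(np.sign(total)), int(np.sign(iface))


def composition_profile(
    all_residues: Iterable[str],
    exposed: Iterable[str],
    interacting: Iterable[str],
) -> pd.DataFrame:
    """Relative amino-acid abundances per category (all/exposed/interacting).

    Inputs are residue-name sequences (one entry per residue); each column
    is normalized to sum to 1.  An empty category is an error.
    """
    cats = {"all": list(all_residues), "exposed": list(exposed), "interacting": list(interacting)}
    out = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=list(cats))
    for cat, names in cats.items():
        if not names:
            raise ValueError(f"empty residue category: {cat!r}")
        counts = pd.Series(names).value_counts()
        for aa in AMINO_ACIDS:
            out.loc[aa, cat] = counts.get(aa, 0)
        out[cat] /= out[cat].sum()
    return out


def residue_representative_points(
    structure: Structure, residues: Iterable[tuple]
) -> dict[tuple, np.ndarray]:
    """Side-chain heavy-atom centroid per residue (CA fallback for GLY).

    ``residues`` are (chain, resnum, resname) keys; charges live on side
    chains, so the side-chain centroid is the natural charge location.
    """
    atoms = structure.atoms
    reps: dict[tuple, np.ndarray] = {}
    grouped = atoms.groupby(["chain", "resnum", "resname"], sort=False)
    wanted = set(residues)
    for key, grp in grouped:
        if key not in wanted:
            continue
        side = grp[~grp["atom"].isin(_BACKBONE)]
        chosen = side if len(side) else grp[grp["atom"] == "CA"]
        if not len(chosen):
            chosen = grp
        reps[key] = chosen[["x", "y", "z"]].to_numpy(dtype=float).mean(axis=0)
    missing = wanted - set(reps)
    if missing:
        raise KeyError(f"residues not found in structure: {sorted(missing)[:5]}")
    return reps


def _charge_class(resname: str, table: Mapping[str, int]) -> str:
    q = residue_charge(resname, table)
    return "-" if q < 0 else ("+" if q > 0 else "0")


def cross_interface_neighbor_stats(
    structure_A: Structure,
    structure_B: Structure,
    interface_A: Iterable[tuple],
    interface_B: Iterable[tuple],
    radius: float = 5.0,
    table: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Percentage of interface residues of each charge class with a
    partner-interface neighbour of each charge class within ``radius``.

    Rows index the residue's own class on one partner, columns the
    neighbour's class on the other; counts are symmetrized over the two
    partners.  Distances are between side-chain centroids.
    """
    table = DEFAULT_CHARGES if table is None else table
    iface_A, iface_B = list(interface_A), list(interface_B)
    if not iface_A or not iface_B:
        raise ValueError("both interface residue sets must be non-empty")
    reps_A = residue_representative_points(structure_A, iface_A)
    reps_B = residue_representative_points(structure_B, iface_B)
    classes = ("-", "+", "0")
    counts = pd.DataFrame(0, index=list(classes), columns=list(classes))
    totals = pd.Series(0, index=list(classes))

    def accumulate(reps_self, reps_other):
        other_keys = list(reps_other)
        other_pts = np.array([reps_other[k] for k in other_keys])
        other_cls = [_charge_class(k[-1], table) for k in other_keys]
        for key, pt in reps_self.items():
            own = _charge_class(key[-1], table)
            totals[own] += 1
            d = np.linalg.norm(other_pts - pt, axis=1)
            near = d <= radius
            for cls in classes:
                if any(near[i] and other_cls[i] == cls for i in range(len(other_keys))):
                    counts.loc[own, cls] += 1

    accumulate(reps_A, reps_B)
    accumulate(reps_B, reps_A)
    pct = counts.astype(float)
    for cls in classes:
        if totals[cls] > 0:
            pct.loc[cls] = 100.0 * counts.loc[cls] / totals[cls]
        else:
            pct.loc[cls] = np.nan
    return pct
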