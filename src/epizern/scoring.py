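"""Complementarity scores, decoy nulls, ROC/AUC and stratification.

Electrostatic complementarity of an interacting pair is measured by F:
the fraction of spatially corresponding SEM pixel pairs with the same
sign.  Complementary patches have potentials of opposite sign facing each
other, so low F means high complementarity; two unrelated patches agree
by chance half the time, so F concentrates near 0.5 for random decoys.
Shape and electrostatic complementarity are alternatively measured as the
Euclidean distance between the 2D Zernike invariant descriptors of the
two patches' projections (SHAPE matrices and CEMs respectively), with
interacting pairs at smaller distances than decoys.

Both channels are evaluated against decoy patch pairs via ROC curves with
the "lower score = interacting" convention, which lets anti-complementary
regimes show up as AUC below 0.5 instead of being silently flipped.
Complexes are stratified by pH (below 5.5 / physiological / above 7.5),
by binding affinity B_a = log10(Kd) (below -9 / -9..-6 / above -6) and
into transient (B_a > -6) versus permanent (B_a < -6) interactions;
boundary values go to the lower bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .interface_patches import (
    ComplexRecord,
    DEFAULT_PATCH_RADIUS,
    Patch,
    extract_patch,
    find_interface,
    patch_center,
    random_patch,
)
from .patch_projection import (
    DEFAULT_CEM_CAP,
    DEFAULT_PIXELS,
    ProjectionMatrix,
    cone_origin,
    em_to_cem,
    em_to_sem,
    fill_masked_pixels,
    orient_pair,
    orient_single,
    project_potential,
    project_shape,
)
from .surface_io import PotentialSurface
from .zernike2d import descriptor_distance, expand, invariants

__all__ = [
    "FScore",
    "ScoreSample",
    "ROCResult",
    "f_score",
    "interacting_f_score",
    "zernike_complementarity",
    "decoy_scores",
    "roc_auc",
    "stratify",
    "affinity_from_kd",
    "transience",
]

CHANNELS = ("F", "zernike_shape", "zernike_electro")


@dataclass
class FScore:
    """Sign-concordance fraction over jointly valid pixel pairs."""

    value: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("F must lie in [0, 1]")
        if self.n_pairs < 1:
            raise ValueError("F needs at least one compared pixel pair")


@dataclass
class ScoreSample:
    """One scored patch pair (interacting or decoy) of a complex."""

    complex_id: str
    score: float
    label: str  # 'interacting' | 'decoy'
    channel: str

    def __post_init__(self) -> None:
        if self.label not in ("interacting", "decoy"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")


@dataclass
class ROCResult:
    """ROC curve and area, lower-score-is-positive convention."""

    auc: float
    curve: np.ndarray  # (k, 2) of (FPR, TPR), monotone from (0,0) to (1,1)
    direction: str = "lower_is_positive"


def f_score(sem_A: ProjectionMatrix, sem_B: ProjectionMatrix) -> FScore:
    """Fraction of jointly masked-in pixel pairs with equal sign."""
    if sem_A.kind != "SEM" or sem_B.kind != "SEM":
        raise ValueError("f_score expects two SEMs")
    if sem_A.grid.shape != sem_B.grid.shape:
        raise ValueError("SEM grids must share shape")
    joint = sem_A.mask & sem_B.mask
    n = int(joint.sum())
    if n == 0:
        raise ValueError("empty joint mask: no pixel pairs to compare")
    same = int(np.sum(sem_A.grid[joint] == sem_B.grid[joint]))
    return FScore(value=same / n, n_pairs=n)


def _patch_arrays(psurf: PotentialSurface, patch: Patch):
    idx = patch.point_indices
    return (
        psurf.surface.points[idx],
        psurf.surface.normals[idx],
        psurf.potential[idx],
    )


def interacting_f_score(
    psurf_A: PotentialSurface,
    psurf_B: PotentialSurface,
    patch_A: Patch,
    patch_B: Patch,
    n_pixels: int = DEFAULT_PIXELS,
) -> FScore:
    """F for an interacting pair using the pair-orientation protocol.

    One common rotation preserves the spatial correspondence of facing
    points, and both EMs share the grid frame (common disk scale).
    """
    pA, nA, vA = _patch_arrays(psurf_A, patch_A)
    pB, nB, vB = _patch_arrays(psurf_B, patch_B)
    opA, opB = orient_pair(pA, nA, pB, nB, values_A=vA, values_B=vB)
    scale = max(
        float(np.hypot(opA.points[:, 0], opA.points[:, 1]).max()),
        float(np.hypot(opB.points[:, 0], opB.points[:, 1]).max()),
    )
    emA = project_potential(opA, n_pixels=n_pixels, disk_scale=scale)
    emB = project_potential(opB, n_pixels=n_pixels, disk_scale=scale)
    return f_score(em_to_sem(emA), em_to_sem(emB))


def _patch_descriptor(
    psurf: PotentialSurface,
    patch: Patch,
    direction: str,
    channel: str,
    order: int,
    n_pixels: int,
    cap: float,
):
    pts, nrm, vals = _patch_arrays(psurf, patch)
    op = orient_single(pts, nrm, values=vals, direction=direction)
    if channel == "shape":
        cone = cone_origin(op)
        matrix = project_shape(op, cone, n_pixels=n_pixels)
    elif channel == "electrostatic":
        matrix = em_to_cem(project_potential(op, n_pixels=n_pixels), cap=cap)
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return invariants(expand(fill_masked_pixels(matrix), order=order))


def zernike_complementarity(
    psurf_A: PotentialSurface,
    psurf_B: PotentialSurface,
    patch_A: Patch,
    patch_B: Patch,
    channel: str = "electrostatic",
    order: int = 20,
    n_pixels: int = DEFAULT_PIXELS,
    cap: float = DEFAULT_CEM_CAP,
) -> float:
    """Zernike-descriptor distance between two contrariwise patches.

    Patches are oriented independently (A up, B down); the shape channel
    expands the SHAPE matrices (45-degree cone origins), the electrostatic
    channel the CEMs.  Smaller distance = higher complementarity.
    """
    dA = _patch_descriptor(psurf_A, patch_A, "up", channel, order, n_pixels, cap)
    dB = _patch_descriptor(psurf_B, patch_B, "down", channel, order, n_pixels, cap)
    return descriptor_distance(dA, dB)


def _decoy_pair_score(
    psurf_A: PotentialSurface,
    psurf_B: PotentialSurface,
    patch_A: Patch,
    patch_B: Patch,
    channel: str,
    order: int,
    n_pixels: int,
    cap: float,
) -> float:
    if channel == "F":
        # decoys follow the single-patch protocol: independent plane fits
        pA, nA, vA = _patch_arrays(psurf_A, patch_A)
        pB, nB, vB = _patch_arrays(psurf_B, patch_B)
        opA = orient_single(pA, nA, values=vA, direction="up")
        opB = orient_single(pB, nB, values=vB, direction="down")
        semA = em_to_sem(project_potential(opA, n_pixels=n_pixels))
        semB = em_to_sem(project_potential(opB, n_pixels=n_pixels))
        return f_score(semA, semB).value
    chan = "shape" if channel == "zernike_shape" else "electrostatic"
    return zernike_complementarity(
        psurf_A, psurf_B, patch_A, patch_B, channel=chan,
        order=order, n_pixels=n_pixels, cap=cap,
    )


def decoy_scores(
    psurf_A: PotentialSurface,
    psurf_B: PotentialSurface,
    n_decoys: int,
    channel: str = "F",
    radius: float = DEFAULT_PATCH_RADIUS,
    rng=None,
    complex_id: str = "",
    order: int = 20,
    n_pixels: int = DEFAULT_PIXELS,
    cap: float = DEFAULT_CEM_CAP,
) -> list[ScoreSample]:
    """Score ``n_decoys`` random patch pairs (one per partner), seeded."""
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    rng = np.random.default_rng(rng)
    out = []
    for _ in range(n_decoys):
        patch_A = random_patch(psurf_A.surface, radius=radius, rng=rng)
        patch_B = random_patch(psurf_B.surface, radius=radius, rng=rng)
        score = _decoy_pair_score(
            psurf_A, psurf_B, patch_A, patch_B, channel, order, n_pixels, cap
        )
        out.append(ScoreSample(complex_id, score, "decoy", channel))
    return out


def roc_auc(
    positives: Sequence[float],
    negatives: Sequence[float],
    direction: str = "lower_is_positive",
) -> ROCResult:
    """ROC curve and AUC with the lower-score-is-positive convention.

    AUC equals the Mann-Whitney statistic P(pos < neg) + 0.5 P(tie); an
    AUC below 0.5 (anti-complementary scores) is reported as is.
    """
    from sklearn.metrics import roc_curve

    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both score sets must be non-empty")
    if direction != "lower_is_positive":
        raise ValueError("only 'lower_is_positive' is supported")
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    # negate so that 'lower score' ranks as 'more positive'
    fpr, tpr, _ = roc_curve(y, -np.concatenate([pos, neg]))
    curve = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(auc=auc, curve=curve, direction=direction)


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

PH_LOW_MAX = 5.5
PH_HIGH_MIN = 7.5
BA_HIGH_MAX = -9.0  # high affinity: Ba < -9 (boundary -> this bin)
BA_MEDIUM_MAX = -6.0  # medium: -9 < Ba < -6; transient/permanent cut


def _ph_bin(ph: float) -> str:
    if ph <= PH_LOW_MAX:
        return "low"
    if ph <= PH_HIGH_MIN:
        return "physiological"
    return "high"


def _ba_bin(ba: float) -> str:
    if ba <= BA_HIGH_MAX:
        return "high"
    if ba <= BA_MEDIUM_MAX:
        return "medium"
    return "low"


def transience(ba: float) -> str:
    """Transient (Ba > -6) vs permanent (Ba < -6); the boundary is permanent."""
    return "transient" if ba > BA_MEDIUM_MAX else "permanent"


def stratify(
    samples: Iterable[ScoreSample],
    records: dict[str, ComplexRecord],
    by: str,
) -> dict[str, list[ScoreSample]]:
    """Group score samples by an annotation of their parent complex.

    ``by`` is one of pH, Ba, dimer_class, structural_class, transience.
    Boundary values of the numeric bins go to the lower bin.  A sample
    whose complex lacks the required annotation is an error naming it.
    """
    groups: dict[str, list[ScoreSample]] = {}
    for s in samples:
        if s.complex_id not in records:
            raise KeyError(f"no annotation record for complex {s.complex_id!r}")
        rec = records[s.complex_id]
        if by == "pH":
            if rec.pH is None:
                raise ValueError(f"complex {s.complex_id!r} lacks pH")
            key = _ph_bin(rec.pH)
        elif by == "Ba":
            if rec.Ba is None:
                raise ValueError(f"complex {s.complex_id!r} lacks Ba/Kd")
            key = _ba_bin(rec.Ba)
        elif by == "transience":
            if rec.Ba is None:
                raise ValueError(f"complex {s.complex_id!r} lacks Ba/Kd")
            key = transience(rec.Ba)
        elif by == "dimer_class":
            if rec.dimer_class is None:
                raise ValueError(f"complex {s.complex_id!r} lacks dimer_class")
            key = rec.dimer_class
        elif by == "structural_class":
            if rec.structural_class is None:
                raise ValueError(f"complex {s.complex_id!r} lacks structural_class")
            key = rec.structural_class
        else:
            raise ValueError(f"unknown stratification {by!r}")
        groups.setdefault(key, []).append(s)
    return groups


def affinity_from_kd(kd: float) -> float:
    """Binding affinity B_a = log10 of the dissociation constant (mol/L)."""
    if kd <= 0:
        raise ValueError("Kd must be positive")
    return float(np.log10(kd))


def score_interface(
    psurf_A: PotentialSurface,
    psurf_B: PotentialSurface,
    channel: str = "F",
    cutoff: float = 6.0,
    radius: float = DEFAULT_PATCH_RADIUS,
    order: int = 20,
    n_pixels: int = DEFAULT_PIXELS,
    cap: float = DEFAULT_CEM_CAP,
    min_points: int = 20,
    complex_id: str = "",
) -> ScoreSample:
    """Score the experimentally interacting patch pair of a complex.

    Finds the interface, centres a patch on each partner's interface
    centroid and applies the channel's protocol (pair orientation for F,
    independent contrariwise orientation for the Zernike channels).
    """
    ann = find_interface(psurf_A.surface, psurf_B.surface, cutoff=cutoff)
    cA = patch_center(ann, psurf_A.surface, side="A")
    cB = patch_center(ann, psurf_B.surface, side="B")
    patch_A = extract_patch(psurf_A.surface, cA, radius=radius, min_points=min_points)
    patch_B = extract_patch(psurf_B.surface, cB, radius=radius, min_points=min_points)
    if channel == "F":
        score = interacting_f_score(psurf_A, psurf_B, patch_A, patch_B, n_pixels).value
    elif channel in ("zernike_shape", "zernike_electro"):
        chan = "shape" if channel == "zernike_shape" else "electrostatic"
        score = zernike_complementarity(
            psurf_A, psurf_B, patch_A, patch_B, channel=chan,
            order=order, n_pixels=n_pixels, cap=cap,
        )
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return ScoreSample(complex_id, score, "interacting", channel)
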