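# Methods

## Model and procedure

`epizern` treats a protein–protein interface as a pair of surface patches
and asks how complementary they are, in shape and in electrostatics.

**Inputs.** Each partner contributes a solvent-accessible surface sampled
as an oriented point cloud (the DMS dialect: surface-point records with
unit normals, nominally 5 points/Å², water probe 1.4 Å) and a scalar
electrostatic potential grid (OpenDX, as written by Poisson–Boltzmann
solvers such as APBS). Potentials are carried opaquely in the solver's
output units (k_BT/e for APBS); no unit conversion is applied, and the
±30 CEM cap is interpreted in those input units. Each surface point takes
the potential of its nearest grid node ("the grid cell corresponding to
the point"); trilinear interpolation is available as an option but is not
the default.

**Interface and patches.** A point of one surface is an interface point
if it lies closer than 6 Å to any point of the partner surface (symmetric
by construction; computed with KD-trees). Interface residues are the
residues tagged by flagged points; surface residues are those with
relative solvent accessibility — supplied SASA divided by the embedded
Tien et al. (2013) theoretical maxima — strictly above 0.25. A patch is
the set of surface points within R = 9 Å of a centre point: the flagged
point nearest the interface centroid for binding patches (ties to the
lowest index), a uniformly drawn surface point for decoys. Patches with
fewer than 20 points are rejected (decoy draws resample, up to a retry
limit) because the downstream plane fit degenerates.

**Orientation.** The best-fit plane of the patch (total least squares via
SVD, normal sign aligned with the patch's mean surface normal) defines
the projection frame.

- *Single-patch protocol* (decoys and both Zernike channels): each patch
  is rotated independently so its plane normal lies along +z ("up") or −z
  ("down"), with the centroid at the origin. The two patches of a pair
  are oriented contrariwise (A up, B down). For a patch whose normal
  already points below the x–y plane, "down" is realised as the minimal
  rotation conjugated through the z-mirror, which keeps the in-plane pose
  of facing patches aligned; for an upward-facing patch it is the exact
  z-reflection of "up", so up/down of the same patch differ exactly by
  z-negation. Descriptor moduli are insensitive to the improper part.
- *Pair protocol* (F score on interacting patches): one common rotation
  takes v = mean(normals of A) − mean(normals of B), normalised, to +z;
  both point sets and normal sets receive the same rotation and a common
  translation (the midpoint of the two patch centroids), so facing points
  keep their x–y correspondence and the two EMs share one grid frame.

**Projections.** Points are projected to the x–y plane and binned on a
25 × 25 grid spanning [−ρ_max, ρ_max]², where ρ_max is the patch's own
maximal projected radius (pair protocol: the larger of the two, so the
grids coincide). Pixels hold the mean of their points' values: the
electrostatic potential (EM) or the distance r to the cone apex C
(shape). C = (0, 0, h) is found by bisection (tolerance 1e-6 rad) so that
the largest angle between the z-axis and a secant from C to any patch
point is 45°; for a flat disk of radius ρ this gives h = ρ exactly, which
the tests use as a closed-form oracle. SEM replaces EM pixels by their
sign (exact zeros are masked out — a sign there would be arbitrary); CEM
clips EM to [−30, +30]. Pixels that received no point are masked.

**Zernike descriptors.** A projection f on the unit disk (radial
coordinate r = ρ/ρ_max) is expanded as

    c_{n'm} = (n'+1)/π ∫₀¹ r dr ∫₀^{2π} dψ  Z*_{n'm}(r, ψ) f(r, ψ),
    Z_{n'm}(r, ψ) = R_{n'm}(r) e^{imψ},
    R_{n'm}(r) = Σ_k (−1)^k (n'−k)! / [k! ((n'+m)/2−k)! ((n'−m)/2−k)!] r^{n'−2k},

for 0 ≤ m ≤ n' ≤ N = 20 with n'−m even (121 indices). The descriptor is
the vector of moduli z_{n'm} = |c_{n'm}|, invariant under in-plane
rotation; patch complementarity is the Euclidean distance between two
descriptors. Reconstruction for validation uses the real-function
convention f = Σ_{m≥0} w_m Re(c_{n'm} Z_{n'm}) with w_0 = 1, w_{m>0} = 2.

**Scores, decoys, ROC.** F is the fraction of jointly valid SEM pixel
pairs with equal sign. Decoy pairs draw one random patch per partner and
are scored with the single-patch protocol; interacting pairs use the pair
protocol for F. ROC curves and AUC (scikit-learn trapezoid, equal to the
Mann–Whitney statistic with half-credit ties) use the
lower-score-is-positive convention for both channels, so
anti-complementary regimes appear as AUC < 0.5 rather than being flipped.
Stratification bins: pH ≤ 5.5 low, ≤ 7.5 physiological, else high;
B_a = log₁₀(K_d) ≤ −9 high affinity, ≤ −6 medium, else low; transient
means B_a > −6. Boundary values go to the lower bin. Dimer classes use
the overlap fraction f = |A∩B| / min(|A|, |B|) of the two binding-region
residue sets (homodimers compared in a shared numbering frame): f ≥ 0.7
IBR-hom, 0.3 ≤ f < 0.7 SBR-hom, f < 0.3 nIBR-hom; heterodimers are
nIBR-het. Structural classes label each partner H or S by majority of
helix vs strand residues (ties → S) and combine order-insensitively.

## Numerical choices

- **Radial polynomials.** Coefficients are exact integer multinomials
  ((n'−k)!/(k!·a!·b!) with k+a+b = n'−k), computed in Python integers and
  converted to float per term. This makes the endpoint identity
  R_{n'm}(1) = 1 hold to machine precision at every order ≤ 20; a
  Jacobi-recurrence evaluation (scipy `eval_jacobi`) serves as an
  independent oracle in the tests.
- **Quadrature.** Matrix expansion uses the pixel-centre midpoint rule
  with the pixel value held constant over its area; pixels straddling the
  unit circle are subdivided 8 × 8 so only their in-disk area contributes.
  The all-or-nothing rim rule couples the field's rim values to the grid
  orientation — every R_{n'm} peaks at r = 1 — and was measured to leave
  2–5% rotation noise in the descriptors; the subdivision removes it.
  The dedicated basis-validation inner product additionally uses a
  composite 2 × 2 Gauss rule on interior pixels (worst orthogonality
  error 1.8e-5 at n' ≤ 8 on a 201² grid, versus 2.6e-3 for the plain
  midpoint rule).
- **Empty pixels.** At 5 points/Å² a 25 × 25 grid has ~2.5 points per
  pixel, so ~8% of in-disk pixels are empty. For the Zernike channels
  these are inpainted by iterated 8-neighbour means before expansion:
  leaving them as zeros punches holes of the field's full magnitude into
  an otherwise smooth function, dominating the spectrum and destroying
  rotation stability (~11% descriptor change under rigid rotation, versus
  ≤ 2% with inpainting). The F score keeps the raw masks — missing pixels
  are excluded from the comparison, never invented.
- **Analytic-field expansion.** `expand_polar` (Gauss–Legendre in r,
  uniform trapezoid in ψ) is spectrally exact for band-limited fields, so
  in-plane rotations shift coefficients by pure phases and descriptors
  are invariant to 1e-9; it backs the analytic branch of the
  rotation-invariance tests, since a square pixel grid is not itself
  rotation-invariant at machine precision.
- **Degenerate inputs.** Collinear patches fail the plane fit with a
  dedicated error; pair orientation fails if the two mean normals cancel;
  cone solving fails if no apex above the patch reaches 45°. Patch
  extraction enforces the 20-point minimum. All-masked matrices cannot be
  expanded.

## Parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| patch radius R | 9 Å | sphere selecting a patch; the scale at which complementarity is probed |
| Zernike order N | 20 | truncation of the expansion; 121 invariants |
| grid | 25 × 25 px | projection resolution (configurable) |
| CEM cap | ±30 (input units) | bounds the field for expansion |
| interface cutoff | 6 Å | point-to-partner distance defining the interface |
| RSA threshold | 0.25 | strict lower bound for surface residues |
| decoys per complex | 100 (CLI default) | null-distribution size |

R and N trade locality against detail: smaller R gives patches too bland
to discriminate, larger R dilutes the interface with non-interacting
surface; low N over-smooths, high N models sampling noise.

## The synthetic generator

`gen_complex` emulates the geometry and fields the real pipeline consumes:
two facing square sheets (half-side R + 3 Å) sampled on a jittered grid at
5 points/Å², with smooth Gaussian-blob relief on one sheet replicated on
the other at a constant 2 Å vertical gap (bumps facing dents, outward unit
normals from the analytic gradient), and a zero-mean Gaussian-blob
potential field φ on A whose negation appears on B except on contiguous
flip-back regions. Blob centres are drawn with a 3σ margin beyond the
sheet so the fields are stationary to the edge. The flip regions are the
superlevel set of an independent smooth field at the empirical quantile
that makes the flipped fraction of the central patch region exactly the
configured `sign_agreement_p` — the ground truth that the pixel-level F
recovers (residual systematic bias ≤ 0.014 toward 0.5 at extreme p, from
pixels mixing flipped and unflipped points). Defaults: bump amplitude
1.5 Å, field correlation length 2.5 Å (flip field 4 Å), potential scale 15
input units — chosen so the relief is resolvable at the pixel scale, a
minority of |φ| values exceed the ±30 cap (exercising CEM clipping), and
flip regions span several pixels. A separate iid ±1 generator
(`gen_random_sem_pair`) provides the exact binomial null for F.

What the generator does **not** emulate: globular curvature and surface
self-occlusion, chemically structured potentials, correlated
SASA/secondary-structure annotations, or experimental noise in K_d and
pH. Passing tests therefore demonstrate the correctness and calibration
of the *measurement pipeline* on controlled inputs, not the real-data
discrimination performance of interfaces, which depends on external
structures and electrostatics solvers.

## Problem sizes

The test and acceptance runs use 50–60 complexes per condition with 10
decoys each (≥ 500 decoys per ROC), 1000 matrix pairs for the F null,
and 20 random rigid rotations for the invariance checks — sizes at which
the measured quantities' standard errors are several times smaller than
the asserted tolerances.

## Known limitations

- Descriptors at N = 20 on a 25 × 25 grid carry a discretisation noise
  floor of ~1–2% (relative ℓ2) under rigid rotation of sparse point
  clouds; comparisons finer than that are not meaningful at this
  resolution.
- The homodimer residue correspondence assumes identical chain numbering;
  differently numbered homodimers need a user-supplied mapping.
- Decoy patches on the synthetic facing sheets are not fully independent
  of the interface field (the whole sheet is interface), which shifts the
  decoy F mean slightly below 0.5 when p < 0.5; on real surfaces decoys
  sample regions unrelated to the partner.
- SASA values are consumed, not computed; secondary-structure labels are
  consumed, not assigned.
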