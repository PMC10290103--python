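# epizern

Electrostatic and shape complementarity of protein–protein interfaces,
measured on 2D projections of molecular-surface patches and compared with
rotation-invariant 2D Zernike descriptors.

## The problem

Whether two protein surface patches bind depends on how well they match —
geometrically (bumps fitting dents) and electrostatically (positive
potential facing negative). Given a solvent-accessible surface sampled as
an oriented point cloud (DMS output, ~5 points/Å²) and the
Poisson–Boltzmann electrostatic potential mapped onto it (APBS OpenDX
grids), `epizern` quantifies the complementarity of a candidate patch pair
and asks whether the experimentally interacting pair stands out from
randomly placed decoy patches.

## The method

A **patch** is the set of surface points within R = 9 Å of a chosen
surface point (the interface centroid for binding patches, a random point
for decoys). Each patch is rotated so its best-fit plane is the x–y plane
and projected onto a 25 × 25 pixel grid:

- **EM** (Electrostatic Matrix): mean potential of the points in each pixel.
- **SEM**: the sign (±1) of each EM pixel.
- **CEM**: the EM clipped to [−30, +30], making the field bounded for the
  Zernike expansion.
- **shape matrix**: mean distance r from the patch points to a cone apex C
  on the z-axis, placed so the cone subtending the patch has half-angle
  θ = 45°.

Two scores compare a pair of patches:

- **F score** — orient the two interacting patches with one common
  rotation (taking the mean of partner A's normals minus partner B's to
  +z, which preserves the spatial correspondence of facing points) and
  count the fraction of SEM pixel pairs with the *same* sign:

  F = #(equal-sign pixel pairs) / #(jointly valid pixel pairs).

  Complementary interfaces have opposite potentials face to face, so low
  F means high electrostatic complementarity; unrelated patches agree by
  chance, F ≈ 0.5.

- **Zernike distance** — expand a projection f(r, ψ) on the unit disk in
  2D Zernike polynomials Z_{n'm}(r, ψ) = R_{n'm}(r) e^{imψ} up to order
  N = 20 (121 parity-restricted indices) and keep the moduli
  z_{n'm} = |c_{n'm}|, which are invariant under in-plane rotation. The
  complementarity of two contrariwise-oriented patches ("up" vs "down") is
  the Euclidean distance between their descriptor vectors — small for
  matching patches, applied to the shape matrices (shape channel) or the
  CEMs (electrostatic channel).

Interacting scores are evaluated against decoy distributions via ROC
curves with the lower-score-is-positive convention (AUC below 0.5 is
reported as such), and complexes can be stratified by pH (< 5.5 /
physiological / > 7.5), by binding affinity B_a = log₁₀(K_d)
(< −9 / −9..−6 / > −6) and into transient (B_a > −6) versus permanent
interactions, or by dimer class (IBR/SBR/nIBR homodimers, heterodimers)
and secondary-structure class (HH/SS/SH).

Because real structures, DMS runs and APBS solutions are not available
offline, the package ships a first-class synthetic generator
(`epizern.synthetic`) that produces facing complementary surfaces with a
controllable cross-interface sign-agreement fraction p — the ground truth
that the measured F recovers.

## Worked example

```python
import numpy as np
from epizern import (GeneratorConfig, gen_complex, extract_patch,
                     decoy_scores, roc_auc)
from epizern.scoring import interacting_f_score

pos, neg = [], []
for s in range(50):
    A, B, truth = gen_complex(GeneratorConfig(sign_agreement_p=0.2, seed=s))
    pa = extract_patch(A.surface, truth["center_A"])
    pb = extract_patch(B.surface, truth["center_B"])
    pos.append(interacting_f_score(A, B, pa, pb).value)
    neg += [d.score for d in decoy_scores(A, B, 10, channel="F", rng=s)]

print(f"mean interacting F = {np.mean(pos):.3f}")
print(f"mean decoy F       = {np.mean(neg):.3f}")
print(f"AUC                = {roc_auc(pos, neg).auc:.3f}")
```

Output:

```
mean interacting F = 0.211
mean decoy F       = 0.448
AUC                = 0.910
```

The interacting patches recover the generated sign-agreement fraction
(p = 0.2): only ~21% of facing pixels share a sign. Decoys sit near
chance level, and the AUC of 0.91 says a low F score almost always
singles out the true interface. The same loop with `channel="zernike_shape"`
or `"zernike_electro"` scores the Zernike channels.

A shell pipeline over files (DMS + OpenDX in, score/ROC tables out):

```
epizern simulate --out runs/demo --n-complexes 5 --seed 7
epizern score    --table runs/demo/complexes.tsv --channel F \
                 --n-decoys 20 --seed 7 --out runs/demo/scores.tsv
epizern roc      --scores runs/demo/scores.tsv --out runs/demo/roc.tsv
```

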