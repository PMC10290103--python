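import numpy as np
import pytest

from epizern import GeneratorConfig, gen_complex, extract_patch
from epizern.surface_io import MolecularSurface, RESIDUE_TAG_DTYPE


def flat_sheet(z: float = 0.0, half_side: float = 6.0, spacing: float = 0.5,
               normal_up: bool = True, chain: str = "A") -> MolecularSurface:
    """Deterministic flat square point sheet at height z."""
    ax = np.arange(-half_side, half_side + spacing / 2, spacing)
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z)])
    nz = 1.0 if normal_up else -1.0
    normals = np.tile([0.0, 0.0, nz], (len(pts), 1))
    tags = np.empty(len(pts), dtype=RESIDUE_TAG_DTYPE)
    for i in range(len(pts)):
        tags[i] = (chain, str(i // 20 + 1), "ALA")
    return MolecularSurface(pts, normals, tags, density=1.0 / spacing**2)


@pytest.fixture(scope="session")
def default_complex():
    """One synthetic complex at the generator's default study conditions."""
    return gen_complex(GeneratorConfig())


@pytest.fixture(scope="session")
def default_patches(default_complex):
    psurf_A, psurf_B, gt = default_complex
    patch_A = extract_patch(psurf_A.surface, gt["center_A"])
    patch_B = extract_patch(psurf_B.surface, gt["center_B"])
    return patch_A, patch_B
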