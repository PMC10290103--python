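"""F score, Zernike complementarity, decoys, ROC and stratification."""

import numpy as np
import pytest

from epizern.interface_patches import ComplexRecord
from epizern.patch_projection import (
    ProjectionMatrix,
    cone_origin,
    fill_masked_pixels,
    orient_single,
    project_shape,
)
from epizern.scoring import (
    ScoreSample,
    affinity_from_kd,
    decoy_scores,
    f_score,
    interacting_f_score,
    roc_auc,
    score_interface,
    stratify,
    transience,
    zernike_complementarity,
)
from epizern.synthetic import GeneratorConfig, gen_complex, gen_random_sem_pair
from epizern.interface_patches import extract_patch
from epizern.zernike2d import descriptor_distance, expand, invariants


def sem(grid):
    grid = np.asarray(grid, dtype=float)
    return ProjectionMatrix("SEM", grid, grid != 0, 0.1, 1.0)


class TestFScore:
    def test_identical_all_positive(self):
        s = sem(np.ones((25, 25)))
        fs = f_score(s, s)
        assert fs.value == 1.0 and fs.n_pairs == 625

    def test_opposite_signs(self):
        a = sem(np.ones((25, 25)))
        b = sem(-np.ones((25, 25)))
        assert f_score(a, b).value == 0.0

    def test_symmetry(self):
        a, b = gen_random_sem_pair(0.7, rng=3)
        assert f_score(a, b).value == f_score(b, a).value

    def test_joint_mask_restricts_pairs(self):
        a = sem(np.ones((4, 4)))
        g = np.ones((4, 4))
        g[0, :] = 0  # masked out in b
        b = sem(g)
        assert f_score(a, b).n_pairs == 12

    def test_empty_joint_mask_error(self):
        a = sem(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="joint mask"):
            f_score(a, a)

    def test_random_pairs_mean_half(self):
        rng = np.random.default_rng(11)
        vals = [f_score(*gen_random_sem_pair(0.5, rng=rng)).value for _ in range(1000)]
        assert abs(np.mean(vals) - 0.5) <= 0.01


class TestZernikeComplementarity:
    def test_own_mirror_complement_is_close(self, default_complex):
        # the complement built from the patch's own points (same footprint,
        # reversed normals, shifted by the gap) must be nearly
        # indistinguishable after contrariwise orientation
        psurf_A, psurf_B, gt = default_complex
        patch = extract_patch(psurf_A.surface, gt["center_A"])
        i = patch.point_indices
        pts, nrm = psurf_A.surface.points[i], psurf_A.surface.normals[i]

        def shape_desc(p_, n_, direction):
            op = orient_single(p_, n_, direction=direction)
            m = fill_masked_pixels(project_shape(op, cone_origin(op)))
            return invariants(expand(m))

        d_up = shape_desc(pts, nrm, "up")
        d_complement = shape_desc(pts + [0, 0, 2.0], -nrm, "down")
        dist = descriptor_distance(d_up, d_complement)
        decoys = decoy_scores(psurf_A, psurf_B, 30, channel="zernike_shape", rng=4)
        median = np.median([d.score for d in decoys])
        assert dist <= 0.05 * median

    def test_identical_flat_patches_near_zero(self):
        cfg = GeneratorConfig(bump_amplitude=0.0, noise_sigma=0.0, seed=9)
        psurf_A, psurf_B, gt = gen_complex(cfg)
        pA = extract_patch(psurf_A.surface, gt["center_A"])
        pB = extract_patch(psurf_B.surface, gt["center_B"])
        d = zernike_complementarity(psurf_A, psurf_B, pA, pB, channel="shape")
        decoys = decoy_scores(psurf_A, psurf_B, 20, channel="zernike_shape", rng=2)
        assert d <= 0.1 * np.median([s.score for s in decoys]) + 1e-6

    def test_cem_sign_flip_modulus_invariance(self, default_complex):
        from epizern.patch_projection import em_to_cem, project_potential

        psurf_A, _, gt = default_complex
        patch = extract_patch(psurf_A.surface, gt["center_A"])
        i = patch.point_indices
        pts, nrm = psurf_A.surface.points[i], psurf_A.surface.normals[i]
        for sign in (1.0, -1.0):
            op = orient_single(pts, nrm, values=sign * psurf_A.potential[i], direction="up")
            cem = fill_masked_pixels(em_to_cem(project_potential(op)))
            desc = invariants(expand(cem))
            if sign > 0:
                d_pos = desc
        assert descriptor_distance(d_pos, desc) == pytest.approx(0.0, abs=1e-12)

    def test_interacting_distance_below_decoys(self, default_complex, default_patches):
        psurf_A, psurf_B, _ = default_complex
        pA, pB = default_patches
        d = zernike_complementarity(psurf_A, psurf_B, pA, pB, channel="shape")
        decoys = decoy_scores(psurf_A, psurf_B, 20, channel="zernike_shape", rng=8)
        assert d < np.median([s.score for s in decoys])


class TestDecoys:
    def test_zero_decoys_empty(self, default_complex):
        psurf_A, psurf_B, _ = default_complex
        assert decoy_scores(psurf_A, psurf_B, 0) == []

    def test_seed_reproducibility(self, default_complex):
        psurf_A, psurf_B, _ = default_complex
        s1 = [d.score for d in decoy_scores(psurf_A, psurf_B, 5, rng=42)]
        s2 = [d.score for d in decoy_scores(psurf_A, psurf_B, 5, rng=42)]
        assert s1 == s2

    def test_decoy_f_mean_half_under_sign_balanced_potentials(self):
        # at sign agreement 0.5 the cross-interface field has no net sign
        # relation, so random patch pairs agree half the time on average
        vals = []
        for s in range(60):
            a, b, _ = gen_complex(GeneratorConfig(sign_agreement_p=0.5, seed=20000 + s))
            vals += [d.score for d in decoy_scores(a, b, 10, channel="F", rng=21000 + s)]
        assert abs(np.mean(vals) - 0.5) <= 0.02


class TestRocAuc:
    def test_worked_example(self):
        res = roc_auc([0.2, 0.4], [0.3, 0.5])
        assert res.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2], [0.3, 0.4]).auc == 1.0

    def test_identical_multisets_half(self):
        scores = [0.1, 0.2, 0.3]
        assert roc_auc(scores, scores).auc == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(7)
        pos = rng.normal(0.4, 0.1, 30).round(2)
        neg = rng.normal(0.5, 0.1, 40).round(2)
        res = roc_auc(pos, neg)
        wins = sum((p < n) + 0.5 * (p == n) for p in pos for n in neg)
        assert res.auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(8)
        res = roc_auc(rng.normal(0.3, 0.1, 20), rng.normal(0.5, 0.1, 20))
        curve = res.curve
        assert tuple(curve[0]) == (0.0, 0.0) and tuple(curve[-1]) == (1.0, 1.0)
        assert np.all(np.diff(curve[:, 0]) >= 0) and np.all(np.diff(curve[:, 1]) >= 0)

    def test_empty_set_error(self):
        with pytest.raises(ValueError):
            roc_auc([], [0.5])


class TestStratification:
    def _samples(self, **kwargs):
        rec = ComplexRecord(pdb_id="x", **kwargs)
        return [ScoreSample("x", 0.4, "interacting", "F")], {"x": rec}

    def test_ph_bins(self):
        for ph, bin_ in ((5.0, "low"), (5.5, "low"), (6.5, "physiological"),
                         (7.5, "physiological"), (8.0, "high")):
            samples, recs = self._samples(pH=ph)
            assert list(stratify(samples, recs, by="pH")) == [bin_]

    def test_ba_bins(self):
        for ba, bin_ in ((-9.5, "high"), (-9.0, "high"), (-7.0, "medium"),
                         (-6.0, "medium"), (-5.0, "low")):
            samples, recs = self._samples(Ba=ba)
            assert list(stratify(samples, recs, by="Ba")) == [bin_]

    def test_transience_cut(self):
        assert transience(-5.0) == "transient"
        assert transience(-7.0) == "permanent"
        assert transience(-6.0) == "permanent"  # boundary to the lower bin

    def test_class_stratification(self):
        samples, recs = self._samples(dimer_class="IBR-hom", structural_class="HH")
        assert list(stratify(samples, recs, by="dimer_class")) == ["IBR-hom"]
        assert list(stratify(samples, recs, by="structural_class")) == ["HH"]

    def test_missing_annotation_names_complex(self):
        samples, recs = self._samples()
        with pytest.raises(ValueError, match="'x'"):
            stratify(samples, recs, by="pH")

    def test_kd_ba_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            ComplexRecord(pdb_id="x", Kd=1e-8, Ba=-5.0)


class TestAffinity:
    def test_log10(self):
        assert affinity_from_kd(1e-9) == pytest.approx(-9.0)
        assert affinity_from_kd(1e-6) == pytest.approx(-6.0)
        assert affinity_from_kd(3.2e-8) == pytest.approx(np.log10(3.2e-8))

    def test_nonpositive_error(self):
        with pytest.raises(ValueError):
            affinity_from_kd(0.0)


class TestScoreInterface:
    def test_f_channel_recovers_ground_truth(self, default_complex):
        psurf_A, psurf_B, gt = default_complex
        s = score_interface(psurf_A, psurf_B, channel="F", complex_id="syn")
        assert s.label == "interacting"
        assert abs(s.score - gt["p"]) < 0.1

    def test_matches_manual_pipeline(self, default_complex, default_patches):
        psurf_A, psurf_B, _ = default_complex
        pA, pB = default_patches
        manual = interacting_f_score(psurf_A, psurf_B, pA, pB).value
        auto = score_interface(psurf_A, psurf_B, channel="F").score
        assert auto == pytest.approx(manual)
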