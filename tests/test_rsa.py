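"""Searchlight geometry, partial Spearman statistics, difference maps."""

import numpy as np
import pytest

from dualhub import glm, rsa, synth
from dualhub.rdm import neural_rdm
from dualhub.rsa import (SearchlightEngine, StatMap, difference_map,
                         partial_spearman, roi_rsa, sphere_offsets,
                         sphere_voxels)

from conftest import random_rdm


def _brute_force_offsets(radius):
    out = []
    r = int(np.ceil(radius))
    for x in range(-r, r + 1):
        for y in range(-r, r + 1):
            for z in range(-r, r + 1):
                if x * x + y * y + z * z <= radius * radius + 1e-9:
                    out.append((x, y, z))
    return set(out)


class TestSphere:
    def test_radius_zero_is_center_voxel(self):
        v = sphere_voxels((3, 3, 3), 0, (7, 7, 7), units="vox")
        assert v.tolist() == [[3, 3, 3]]

    def test_radius_four_matches_lattice_enumeration(self):
        got = {tuple(v - 10) for v in
               sphere_voxels((10, 10, 10), 4, (21, 21, 21), units="vox")}
        assert got == _brute_force_offsets(4.0)

    def test_mm_sphere_matches_voxel_enumeration(self):
        from dualhub.volumes import default_affine
        aff = default_affine((21, 21, 21), voxel_mm=3.0)
        center_mm = aff[:3, :3] @ np.array([10, 10, 10]) + aff[:3, 3]
        got = {tuple(v - 10) for v in
               sphere_voxels(center_mm, 10.0, (21, 21, 21), affine=aff,
                             units="mm")}
        assert got == _brute_force_offsets(10.0 / 3.0)

    def test_out_of_mask_center_signalled(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        with pytest.raises(ValueError, match="empty intersection"):
            sphere_voxels((2, 2, 2), 1, (5, 5, 5), units="vox", mask=mask)


class TestPartialSpearman:
    def test_closed_form_oracle_four_concepts(self, rng):
        from scipy.stats import rankdata
        a, b, c = (random_rdm(4, rng) for _ in range(3))
        rho, z = partial_spearman(a, b, c)
        rx, ry, rz = (rankdata(m.vector()) for m in (a, b, c))
        rxy = np.corrcoef(rx, ry)[0, 1]
        rxz = np.corrcoef(rx, rz)[0, 1]
        ryz = np.corrcoef(ry, rz)[0, 1]
        oracle = (rxy - rxz * ryz) / np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
        assert rho == pytest.approx(oracle, abs=1e-12)
        assert z == pytest.approx(np.arctanh(rho), abs=1e-12)

    def test_degenerate_covariate_falls_back_to_plain_spearman(self, rng):
        a = random_rdm(5, rng)
        import dualhub.rdm as rdm_mod
        const = rdm_mod.RDM(a.labels, np.ones((5, 5)) - np.eye(5))
        rho, _ = partial_spearman(a, a, const)
        assert rho == pytest.approx(1.0)

    def test_zero_rho_gives_zero_z(self, rng):
        # build target whose ranks are orthogonal to neural ranks by
        # symmetry: reversed ranks
        a = random_rdm(6, rng)
        rho, z = partial_spearman(a, a, random_rdm(6, rng))
        assert np.isfinite(z)
        assert rsa.fisher_z(0.0) == 0.0

    def test_rank_invariance_under_monotone_transform(self, rng):
        a, b, c = (random_rdm(8, rng) for _ in range(3))
        rho1, _ = partial_spearman(a, b, c)
        cube = lambda m: type(m)(m.labels, (m.values + 1.0) ** 3
                                 - np.diag(np.diag((m.values + 1.0) ** 3)))
        rho2, _ = partial_spearman(cube(a), cube(b), cube(c))
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_perfect_confound_is_zero_or_missing(self, rng):
        a, b = random_rdm(7, rng), random_rdm(7, rng)
        rho, _ = partial_spearman(a, b, b)       # covariate == target
        assert np.isnan(rho) or abs(rho) < 1e-8

    def test_label_mismatch_rejected(self, rng):
        a = random_rdm(4, rng)
        b = random_rdm(4, rng, labels=["x0", "x1", "x2", "x3"])
        with pytest.raises(ValueError, match="labels"):
            partial_spearman(a, b, a)


class TestSearchlight:
    def _noise_betas(self, rng, n_concepts=10, shape=(8, 8, 8)):
        mask = np.ones(shape, dtype=bool)
        labels = [f"c{i:02d}" for i in range(n_concepts)]
        P = rng.normal(size=(n_concepts, mask.sum()))
        return glm.BetaMaps(labels, P, mask, np.eye(4))

    def test_engine_matches_per_sphere_loop(self, rng):
        betas = self._noise_betas(rng)
        target, cov = random_rdm(10, rng), random_rdm(10, rng)
        eng = SearchlightEngine(betas, betas.labels, radius_vox=2,
                                min_voxels=5)
        smap = eng.stat_map(target, cov)
        for center in [(0, 0, 0), (4, 4, 4), (7, 2, 5), (3, 6, 1)]:
            vox = sphere_voxels(center, 2, betas.mask.shape, units="vox",
                                mask=betas.mask)
            flat = np.ravel_multi_index(vox.T, betas.mask.shape)
            nr = neural_rdm(betas.betas[:, flat], labels=betas.labels)
            _, z = partial_spearman(nr, target, cov)
            assert smap.values[center] == pytest.approx(z, abs=1e-10)

    def test_small_spheres_are_missing_not_zero(self, rng):
        betas = self._noise_betas(rng, shape=(4, 4, 4))
        target, cov = random_rdm(10, rng), random_rdm(10, rng)
        eng = SearchlightEngine(betas, betas.labels, radius_vox=1,
                                min_voxels=7)
        smap = eng.stat_map(target, cov)
        # corner spheres have 4 voxels < min_voxels -> NaN; interior
        # spheres have the full 7-voxel cross and are evaluated
        assert np.isnan(smap.values[0, 0, 0])
        assert np.isfinite(smap.values[2, 2, 2])

    def test_noiseless_plant_saturates_to_clipped_z(self):
        # region == the searchlight sphere at its center: the sphere then
        # sees the whole embedded geometry and the semantic RDM exactly
        cs = synth.make_concept_space(8, 8, dim=5, seed=11,
                                      exemplar_jitter=0.0)
        shape = (9, 9, 9)
        vox = sphere_voxels((4, 4, 4), 2, shape, units="vox")
        reg = synth.RegionSignal(vox, 1.0, 1.0, 0.0)
        pat = synth.planted_patterns(cs, reg, np.random.default_rng(1))
        full = np.zeros((16, np.prod(shape)))
        flat = np.ravel_multi_index(vox.T, shape)
        full[:, flat] = pat
        mask = np.ones(shape, dtype=bool)
        betas = glm.BetaMaps(cs.concept_ids, full, mask, np.eye(4))
        ids = cs.ids_of_type("event")
        idx = cs.index_of(ids)
        from dualhub.rdm import semantic_rdm, visual_rdm
        sem = semantic_rdm(cs.semantic_vectors[idx], labels=ids)
        vis = visual_rdm(cs.exemplar_features[idx], labels=ids)
        eng = SearchlightEngine(betas, ids, radius_vox=2, min_voxels=5)
        z_center = eng.stat_map(sem, vis).values[4, 4, 4]
        assert z_center == pytest.approx(np.arctanh(1 - 1e-12), rel=1e-6)

    def test_translation_equivariance_in_interior(self, rng):
        shape = (10, 10, 10)
        mask = np.ones(shape, dtype=bool)
        labels = [f"c{i}" for i in range(8)]
        P = rng.normal(size=(8, *shape))
        shifted = np.roll(P, 1, axis=1)
        target, cov = random_rdm(8, rng), random_rdm(8, rng)
        m1 = SearchlightEngine(
            glm.BetaMaps(labels, P.reshape(8, -1), mask, np.eye(4)),
            labels, 2, 5).stat_map(target, cov).values
        m2 = SearchlightEngine(
            glm.BetaMaps(labels, shifted.reshape(8, -1), mask, np.eye(4)),
            labels, 2, 5).stat_map(target, cov).values
        np.testing.assert_allclose(m2[3:8, 2:8, 2:8], m1[2:7, 2:8, 2:8],
                                   atol=1e-10)

    def test_pure_noise_mean_z_near_zero(self, rng):
        target, cov = random_rdm(10, rng), random_rdm(10, rng)
        means = []
        for _ in range(30):
            betas = self._noise_betas(rng, shape=(6, 6, 6))
            eng = SearchlightEngine(betas, betas.labels, 2, 5)
            means.append(np.nanmean(eng.stat_map(target, cov).values))
        assert abs(np.mean(means)) < 0.02


class TestROIAndDifference:
    def test_roi_on_whole_noiseless_region_gives_rho_one(self):
        cs = synth.make_concept_space(8, 8, dim=5, seed=13,
                                      exemplar_jitter=0.0)
        shape = (7, 7, 7)
        vox = sphere_voxels((3, 3, 3), 3, shape, units="vox")
        reg = synth.RegionSignal(vox, 1.0, 1.0, 0.0)
        pat = synth.planted_patterns(cs, reg, np.random.default_rng(2))
        full = np.zeros((16, np.prod(shape)))
        full[:, np.ravel_multi_index(vox.T, shape)] = pat
        betas = glm.BetaMaps(cs.concept_ids, full,
                             np.ones(shape, dtype=bool), np.eye(4))
        ids = cs.ids_of_type("event")
        idx = cs.index_of(ids)
        from dualhub.rdm import semantic_rdm, visual_rdm
        sem = semantic_rdm(cs.semantic_vectors[idx], labels=ids)
        vis = visual_rdm(cs.exemplar_features[idx], labels=ids)
        rho, _ = roi_rsa(betas, vox, sem, vis)
        assert rho == pytest.approx(1.0, abs=1e-9)

    def test_paper_rois_instantiate_on_mni_like_grid(self, rng):
        from dualhub.volumes import default_affine
        shape = (61, 73, 61)
        aff = default_affine(shape, voxel_mm=3.0)
        for roi in rsa.PAPER_ROIS:
            vox = sphere_voxels(roi.center_mm, roi.radius_mm, shape,
                                affine=aff, units="mm")
            assert len(vox) > 10

    def test_roi_outside_mask_signalled(self, rng):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[0, 0, 0] = True
        betas = glm.BetaMaps(["a", "b", "c"], rng.normal(size=(3, 1)),
                             mask, np.eye(4))
        t = random_rdm(3, rng, labels=["a", "b", "c"])
        with pytest.raises(ValueError):
            roi_rsa(betas, np.array([[4, 4, 4]]), t, t)

    def test_difference_map_arithmetic_and_missing(self):
        e = StatMap(np.array([[[0.30, np.nan]]]), "event", 3)
        o = StatMap(np.array([[[0.12, 0.5]]]), "object", 3)
        d = difference_map(e, o)
        assert d.values[0, 0, 0] == pytest.approx(0.18)
        assert np.isnan(d.values[0, 0, 1])
        assert d.concept_type == "difference"
        same = difference_map(o, o)
        assert np.allclose(same.values, 0.0)
        with pytest.raises(ValueError, match="grids"):
            difference_map(e, StatMap(np.zeros((2, 2, 2)), "object", 3))
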