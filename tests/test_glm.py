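"""Design construction, OLS/LSS estimation, smoothing, ROI summaries."""

import numpy as np
import pandas as pd
import pytest

from dualhub import glm
from dualhub.volumes import VolumeSeries, default_affine


def _trials(rows):
    return pd.DataFrame([dict(onset=o, duration=d, concept_id=c,
                              condition=cond, block=1, catch_follows=False)
                         for o, d, c, cond in rows],
                        columns=["onset", "duration", "concept_id",
                                 "condition", "block", "catch_follows"])


class TestCanonicalHRF:
    def test_zero_at_origin_unit_peak_five_second_mode(self):
        h = glm.canonical_hrf(0.001)
        assert h[0] == 0.0
        assert h.max() == pytest.approx(1.0, abs=1e-9)
        # gamma(shape 6, scale 1) mode is (k-1)*theta = 5 s; the undershoot
        # term shifts it only marginally
        assert np.argmax(h) * 0.001 == pytest.approx(5.0, abs=0.05)

    def test_rejects_nonpositive_tr(self):
        with pytest.raises(ValueError):
            glm.canonical_hrf(0.0)


class TestDesignMatrix:
    def test_dct_count_matches_cutoff_formula(self):
        # floor(2 * 858 * 1.7 / 180) = floor(16.206) = 16
        assert glm.dct_highpass_basis(858, 1.7, 180.0).shape[1] == 16
        X = glm.build_design_matrix(_trials([(10, 2.5, "a", "event")]),
                                    1.7, 858)
        assert sum(r == "nuisance_hpf" for r in X.roles) == 16

    def test_empty_trials_only_nuisance_and_constant(self):
        X = glm.build_design_matrix(_trials([]), 2.0, 100)
        assert set(X.roles) == {"nuisance_hpf", "constant"}
        assert X.names[-1] == "constant"

    def test_task_column_equals_direct_convolution(self):
        tr, n_vol, dt = 2.0, 120, 0.1
        X = glm.build_design_matrix(_trials([(17.0, 2.5, "a", "event")]),
                                    tr, n_vol, dt=dt)
        # independent oracle: explicit discrete convolution loop
        n_fine = int(np.ceil(n_vol * tr / dt)) + 1
        box = np.zeros(n_fine)
        box[int(round(17.0 / dt)):int(round(19.5 / dt))] = 1.0
        kern = glm.canonical_hrf(dt)
        conv = np.zeros(n_fine)
        for i in range(n_fine):
            for j in range(len(kern)):
                if 0 <= i - j < n_fine:
                    conv[i] += box[i - j] * kern[j] * dt
        sampled = conv[np.round(np.arange(n_vol) * tr / dt).astype(int)]
        np.testing.assert_allclose(X.column("event"), sampled, atol=1e-10)

    def test_onset_beyond_run_rejected_naming_trial(self):
        with pytest.raises(ValueError, match="late_concept"):
            glm.build_design_matrix(
                _trials([(999.0, 2.5, "late_concept", "event")]), 2.0, 100)

    def test_task_columns_invariant_to_trial_order(self):
        rows = [(10, 2.5, "a", "event"), (30, 2.5, "b", "object"),
                (50, 2.5, "c", "event")]
        X1 = glm.build_design_matrix(_trials(rows), 2.0, 60)
        X2 = glm.build_design_matrix(_trials(rows[::-1]), 2.0, 60,
                                     condition_order=["event", "object"])
        np.testing.assert_allclose(X1.column("event"), X2.column("event"))
        np.testing.assert_allclose(X1.column("object"), X2.column("object"))


class TestFitOLS:
    def test_noiseless_exact_recovery_and_residual_orthogonality(self, rng):
        X = glm.build_design_matrix(
            _trials([(5, 2.5, "a", "event"), (25, 2.5, "b", "object")]),
            2.0, 80)
        beta = rng.normal(size=(len(X.names), 30))
        Y = X.X @ beta
        fit = glm.fit_ols(Y, X)
        np.testing.assert_allclose(fit.betas, beta, atol=1e-10)
        Yn = Y + rng.normal(size=Y.shape)
        fitn = glm.fit_ols(Yn, X)
        resid = Yn - X.X @ fitn.betas
        scale = np.abs(X.X).max() * np.abs(Yn).max()
        assert np.max(np.abs(X.X.T @ resid)) < 1e-8 * scale

    def test_matches_normal_equations_oracle(self):
        X = glm.DesignMatrix(["x", "constant"],
                             np.array([[1.0, 1], [2, 1], [3, 1], [4, 1]]),
                             ["task", "constant"])
        y = np.array([[2.0], [2.5], [4.0], [4.5]])
        fit = glm.fit_ols(y, X)
        expected = np.linalg.inv(X.X.T @ X.X) @ X.X.T @ y
        np.testing.assert_allclose(fit.betas, expected, atol=1e-12)

    def test_orthogonal_response_gives_zero_task_betas(self, rng):
        X = glm.build_design_matrix(_trials([(5, 2.5, "a", "event")]), 2.0, 50)
        # y = multiple of the constant plus a component orthogonal to the
        # whole column space: only the constant's beta can be nonzero
        raw = rng.normal(size=50)
        resid = raw - X.X @ (np.linalg.pinv(X.X) @ raw)
        y = 5.0 * np.ones(50) + resid
        fit = glm.fit_ols(y[:, None], X)
        assert abs(fit.betas[0, 0]) < 1e-8
        assert fit.betas[-1, 0] == pytest.approx(5.0, abs=1e-8)

    def test_rank_deficiency_names_collinear_columns(self):
        X = glm.DesignMatrix(
            ["a", "a_copy", "constant"],
            np.column_stack([np.arange(10.0), np.arange(10.0), np.ones(10)]),
            ["task", "task", "constant"])
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            glm.fit_ols(np.zeros((10, 2)), X)


class TestContrastAndROI:
    def _betamaps(self, vals):
        mask = np.ones((2, 2, 1), dtype=bool)
        return glm.BetaMaps(list(vals), np.array([np.full(4, v)
                                                  for v in vals.values()]),
                            mask, np.eye(4))

    def test_contrast_arithmetic(self):
        b = self._betamaps({"event": 2.0, "object": 0.5})
        c = glm.contrast_map(b, {"event": 1.0, "object": -1.0})
        assert np.allclose(c, 1.5)
        same = self._betamaps({"event": 1.3, "object": 1.3})
        assert np.allclose(glm.contrast_map(
            same, {"event": 1.0, "object": -1.0}), 0.0)
        only = glm.contrast_map(b, {"event": 1.0})
        np.testing.assert_allclose(only, b.map("event"))
        with pytest.raises(KeyError):
            glm.contrast_map(b, {"nonexistent": 1.0})

    def test_roi_mean_matches_loop(self, rng):
        mask = np.ones((4, 4, 4), dtype=bool)
        vals = rng.normal(size=(2, 64))
        b = glm.BetaMaps(["event", "object"], vals, mask, np.eye(4))
        roi = np.array([[0, 0, 0], [1, 2, 3], [3, 3, 3]])
        means = glm.roi_mean_beta(b, roi)
        stack = b.stack()
        for i, lab in enumerate(["event", "object"]):
            loop = np.mean([stack[i][tuple(v)] for v in roi])
            assert means[lab] == pytest.approx(loop, abs=1e-12)
        # two-voxel arithmetic example
        b2 = glm.BetaMaps(["x"], np.arange(64.0)[None, :], mask, np.eye(4))
        got = glm.roi_mean_beta(b2, np.array([[0, 0, 1], [0, 0, 3]]))
        assert got["x"] == pytest.approx(2.0)

    def test_empty_roi_rejected(self):
        b = self._betamaps({"event": 1.0})
        b.mask[:] = False
        b2 = glm.BetaMaps(["event"], np.zeros((1, 0)), b.mask, np.eye(4))
        with pytest.raises(ValueError, match="empty intersection"):
            glm.roi_mean_beta(b2, np.array([[0, 0, 0]]))


class TestLSS:
    def test_orthogonal_trials_match_lsa_and_truth(self, rng):
        # disjoint HRF supports -> trial regressors mutually orthogonal
        tr, n_vol = 2.0, 200
        ids = [f"c{i}" for i in range(6)]
        trials = _trials([(10 + 40.0 * i, 2.5, c, "event")
                          for i, c in enumerate(ids)])
        cols = [glm._convolved_column(np.array([10 + 40.0 * i]),
                                      np.array([2.5]), tr, n_vol)
                for i in range(6)]
        beta = rng.normal(size=(6, 40))
        Y = np.column_stack(cols) @ beta
        vols = VolumeSeries(Y.T.reshape(40, 1, 1, n_vol),
                            default_affine((40, 1, 1)), tr)
        lss = glm.lss_betas(vols, trials, ids, hpf_cutoff=0)
        lsa = (np.linalg.pinv(np.column_stack(cols + [np.ones(n_vol)])) @ Y)[:6]
        np.testing.assert_allclose(lss.betas, lsa, atol=1e-8)
        np.testing.assert_allclose(lss.betas, beta, atol=1e-8)

    def test_single_concept_run_equals_plain_glm(self, rng):
        tr, n_vol = 2.0, 60
        trials = _trials([(8.0, 2.5, "only", "event"),
                          (30.0, 2.5, "only", "event")])
        col = glm._convolved_column(np.array([8.0, 30.0]),
                                    np.array([2.5, 2.5]), tr, n_vol)
        y = 2.5 * col + 0.1 * rng.normal(size=n_vol)
        vols = VolumeSeries(y.reshape(1, 1, 1, n_vol),
                            default_affine((1, 1, 1)), tr)
        lss = glm.lss_betas(vols, trials, ["only"], hpf_cutoff=0)
        hp = np.column_stack([col, np.ones(n_vol)])
        ref = (np.linalg.pinv(hp) @ y)[0]
        assert lss.betas[0, 0] == pytest.approx(ref, abs=1e-10)

    def test_missing_concept_rejected(self, rng):
        trials = _trials([(8.0, 2.5, "a", "event")])
        vols = VolumeSeries(rng.normal(size=(1, 1, 1, 40)),
                            default_affine((1, 1, 1)), 2.0)
        with pytest.raises(ValueError, match="ghost"):
            glm.lss_betas(vols, trials, ["a", "ghost"])

    def test_one_map_per_concept(self, concepts_small, design_small):
        from dualhub import synth
        spec = synth.SignalSpec(noise_sd=0.3, drift_amplitude=0.0,
                                subject_sd=0.0)
        vols = synth.simulate_subject(concepts_small, design_small,
                                      (3, 3, 3), spec, tr=1.7, seed=0)
        maps = glm.lss_betas(vols, design_small, concepts_small.concept_ids)
        assert maps.labels == concepts_small.concept_ids
        assert maps.betas.shape == (concepts_small.n, 27)


class TestGaussianSmooth:
    def test_zero_width_is_identity(self, rng):
        f = rng.normal(size=(5, 5, 5))
        np.testing.assert_array_equal(
            glm.gaussian_smooth(f, 0.0, default_affine((5, 5, 5))), f)

    def test_constant_field_unchanged_inside_mask(self, rng):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        f = np.where(mask, 3.25, rng.normal(size=(8, 8, 8)))
        s = glm.gaussian_smooth(f, 8.0, default_affine((8, 8, 8)), mask=mask)
        np.testing.assert_allclose(s[mask], 3.25, atol=1e-10)
        assert np.isnan(s[~mask]).all()

    def test_impulse_matches_dense_convolution(self):
        # impulse far from every edge, so boundary handling cannot matter
        n = 17
        f = np.zeros((n, n, n))
        f[8, 8, 8] = 1.0
        aff = default_affine((n, n, n), voxel_mm=3.0)
        s = glm.gaussian_smooth(f, 8.0, aff)
        sigma = 8.0 / (2 * np.sqrt(2 * np.log(2))) / 3.0
        radius = int(4.0 * sigma + 0.5)            # separable truncation
        ax = np.arange(n) - 8.0
        k1 = np.where(np.abs(ax) <= radius,
                      np.exp(-ax ** 2 / (2 * sigma ** 2)), 0.0)
        k1 /= k1.sum()
        dense = np.einsum("i,j,k->ijk", k1, k1, k1)
        np.testing.assert_allclose(s, dense, atol=1e-12)

    def test_full_mask_mean_preserved(self, rng):
        f = rng.normal(size=(10, 10, 10)) + 5.0
        s = glm.gaussian_smooth(f, 8.0, default_affine((10, 10, 10)))
        assert abs(s.mean() - f.mean()) / abs(f.mean()) < 1e-6

    def test_sheared_affine_rejected(self, rng):
        aff = np.eye(4)
        aff[0, 1] = 0.5
        with pytest.raises(ValueError, match="axis-aligned"):
            glm.gaussian_smooth(rng.normal(size=(4, 4, 4)), 6.0, aff)
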