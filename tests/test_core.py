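import numpy as np
import pytest

from congrad import (BoldRun, GradientSet, compute_fingerprints, eta2_affinity,
                     generate_bold, laplacian_eigenmaps, make_scenario,
                     normalize_gradients, planted_modes, subject_gradients)
from congrad.core import group_gradients
from congrad.errors import (ArgumentError, ConnectivityError,
                            DegenerateModeError, DimensionError)


def _toy_run(rng, t=60, n_roi=5, n_tgt=8):
    shape = (6, 6, 6)
    roi = np.zeros(shape, bool)
    gm = np.zeros(shape, bool)
    roi.ravel()[:n_roi] = True
    gm.ravel()[100:100 + n_tgt] = True
    data = rng.normal(size=(t, n_roi + n_tgt))
    return BoldRun(data, roi, gm, np.eye(4))


class TestFingerprints:
    def test_identical_and_anticorrelated_series(self, rng):
        run = _toy_run(rng)
        inb = run.inbrain_mask
        roi_cols = np.where(run.roi_mask[inb])[0]
        tgt_cols = np.where((run.gm_mask & ~run.roi_mask)[inb])[0]
        run.data[:, tgt_cols[0]] = run.data[:, roi_cols[0]]
        run.data[:, tgt_cols[1]] = -run.data[:, roi_cols[1]]
        fp = compute_fingerprints(run)
        assert fp[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert fp[1, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        run = _toy_run(rng, t=40, n_roi=20, n_tgt=15)
        fp = compute_fingerprints(run)
        roi, tgt = run.roi_data(), run.target_data()
        for i in range(20):
            for j in range(15):
                assert fp[i, j] == pytest.approx(
                    np.corrcoef(roi[:, i], tgt[:, j])[0, 1], abs=1e-10)

    def test_zero_variance_voxel_imputed(self, rng):
        run = _toy_run(rng)
        inb = run.inbrain_mask
        roi_cols = np.where(run.roi_mask[inb])[0]
        run.data[:, roi_cols[2]] = 5.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            fp = compute_fingerprints(run)
        assert np.all(fp[2] == 0.0)

    def test_reduce_dim_shapes_and_bounds(self, rng):
        run = _toy_run(rng, t=30)
        fp = compute_fingerprints(run, reduce_dim=4)
        assert fp.shape == (5, 4)
        assert np.all(np.abs(fp) <= 1.0)
        with pytest.raises(ArgumentError):
            compute_fingerprints(run, reduce_dim=30)


class TestEta2:
    def test_identical_rows_give_one(self):
        f = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert eta2_affinity(f)[0, 1] == pytest.approx(1.0)

    def test_unit_vectors_give_zero(self):
        f = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert eta2_affinity(f)[0, 1] == pytest.approx(0.0, abs=1e-14)

    def test_matches_brute_force_oracle(self, rng):
        f = rng.normal(size=(10, 30))
        eta = eta2_affinity(f)
        for a in range(10):
            for b in range(10):
                m = (f[a] + f[b]) / 2.0
                gm = np.mean([f[a], f[b]])
                num = np.sum((f[a] - m) ** 2 + (f[b] - m) ** 2)
                den = np.sum((f[a] - gm) ** 2 + (f[b] - gm) ** 2)
                expected = 1.0 if a == b else 1.0 - num / den
                assert eta[a, b] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(eta, eta.T)
        assert np.all((eta >= 0) & (eta <= 1))

    def test_degenerate_identical_constant_rows(self):
        f = np.array([[2.0, 2.0], [2.0, 2.0]])
        assert eta2_affinity(f)[0, 1] == 1.0


class TestLaplacianEigenmaps:
    def test_path_graph_fiedler_is_monotone(self):
        n = 6
        w = np.zeros((n, n))
        for i in range(n - 1):
            w[i, i + 1] = w[i + 1, i] = 1.0
        np.fill_diagonal(w, 1.0)
        grads = laplacian_eigenmaps(w, 1)
        diffs = np.diff(grads.modes[:, 0])
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_disconnected_graph_reports_components(self):
        w = np.zeros((6, 6))
        w[:3, :3] = 1.0
        w[3:, 3:] = 1.0
        with pytest.raises(ConnectivityError) as exc:
            laplacian_eigenmaps(w, 1)
        assert exc.value.component_sizes == (3, 3)

    @pytest.mark.parametrize("kind", ["random-walk", "unnormalized"])
    def test_matches_dense_eigendecomposition(self, rng, kind):
        from scipy import linalg
        n = 15
        f = rng.normal(size=(n, 25))
        w = eta2_affinity(f)
        grads = laplacian_eigenmaps(w, 4, laplacian_kind=kind)
        wd = w.copy()
        np.fill_diagonal(wd, 0.0)
        d = wd.sum(axis=1)
        lap = np.diag(d) - wd
        if kind == "random-walk":
            vals, vecs = linalg.eigh(lap, np.diag(d))
        else:
            vals, vecs = linalg.eigh(lap)
        assert np.max(np.abs(grads.eigenvalues - vals[1:5])) < 1e-8
        angles = linalg.subspace_angles(grads.modes, vecs[:, 1:5])
        assert np.max(angles) < 1e-6

    def test_modes_orthogonal_in_solver_inner_product(self, rng):
        w = eta2_affinity(rng.normal(size=(20, 30)))
        grads = laplacian_eigenmaps(w, 5)
        wd = w.copy()
        np.fill_diagonal(wd, 0.0)
        d = wd.sum(axis=1)
        gram = grads.modes.T @ (d[:, None] * grads.modes)
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-6
        assert np.all(np.diff(grads.eigenvalues) > 0)

    def test_permutation_equivariance(self, rng):
        w = eta2_affinity(rng.normal(size=(18, 25)))
        perm = rng.permutation(18)
        g1 = laplacian_eigenmaps(w, 3)
        g2 = laplacian_eigenmaps(w[np.ix_(perm, perm)], 3)
        # same eigenvalues; modes equal up to permutation and sign
        assert np.allclose(g1.eigenvalues, g2.eigenvalues, atol=1e-10)
        for k in range(3):
            r = np.corrcoef(g1.modes[perm, k], g2.modes[:, k])[0, 1]
            assert abs(r) > 1 - 1e-8

    def test_n_modes_bounds(self, rng):
        w = eta2_affinity(rng.normal(size=(6, 10)))
        with pytest.raises(ArgumentError):
            laplacian_eigenmaps(w, 6)


class TestNormalize:
    def test_affine_rescale_to_unit_range(self):
        g = GradientSet(np.array([[-2.0, 1.0], [0.0, 2.0], [2.0, 5.0]]),
                        [0.1, 0.2])
        out = normalize_gradients(g)
        assert np.allclose(out.modes[:, 0], [0.0, 0.5, 1.0])
        assert out.modes.min() == 0.0 and out.modes.max() == 1.0
        assert np.array_equal(out.eigenvalues, g.eigenvalues)

    def test_already_unit_range_unchanged(self):
        g = GradientSet(np.array([[0.0], [0.25], [1.0]]), [0.3])
        assert np.allclose(normalize_gradients(g).modes, g.modes)

    def test_constant_mode_raises(self):
        g = GradientSet(np.ones((4, 1)), [0.5])
        with pytest.raises(DegenerateModeError):
            normalize_gradients(g)

    def test_normalization_preserves_correlation(self, rng):
        modes = rng.normal(size=(50, 3))
        ref = rng.normal(size=50)
        g = normalize_gradients(GradientSet(modes, [1, 2, 3]))
        for k in range(3):
            r_raw = np.corrcoef(modes[:, k], ref)[0, 1]
            r_norm = np.corrcoef(g.modes[:, k], ref)[0, 1]
            assert abs(r_raw - r_norm) < 1e-12


class TestSubjectGroupPaths:
    def test_group_of_identical_runs_equals_subject(self, rng):
        sc = make_scenario(n_subjects=3, n_timepoints=80)
        truth = planted_modes(sc)
        run = generate_bold(sc, 0, truth)
        single = subject_gradients(run, 3)
        group = group_gradients([run, run, run], 3)
        assert np.max(np.abs(single.modes - group.modes)) < 1e-8

    def test_requested_mode_count_and_ordering(self, runs):
        g = subject_gradients(runs[0], 6)
        assert g.n_modes == 6
        assert np.all(np.diff(g.eigenvalues) > 0)

    def test_subject_level_recovery_of_planted_modes(self, scenario, truth):
        g = subject_gradients(generate_bold(scenario, 0, truth), 2)
        for k in range(2):
            best = max(abs(np.corrcoef(g.modes[:, j],
                                       truth.mode_matrix[:, k])[0, 1])
                       for j in range(2))
            assert best > 0.9

    def test_mask_mismatch_rejected(self, rng):
        sc = make_scenario(n_subjects=2, n_timepoints=50)
        sc2 = make_scenario(n_subjects=2, n_timepoints=50,
                            grid_shape=(24, 24, 26))
        r1 = generate_bold(sc, 0)
        r2 = generate_bold(sc2, 0)
        with pytest.raises(DimensionError):
            group_gradients([r1, r2], 2)
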