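"""Cosine affinity, Laplacian eigenmaps, variance explained, Procrustes."""

import numpy as np
import pytest
import scipy.linalg
from scipy.stats import spearmanr

import subgrad as sg
from subgrad.connectivity import FCMatrix
from subgrad.gradients import (
    AffinityMatrix,
    cosine_affinity,
    orient_to_axis,
)


def _affinity_from_rows(rows):
    fc = FCMatrix(values=np.asarray(rows, float), sparsified=True)
    return cosine_affinity(fc)


def _dense_oracle(W, n_components):
    """Full dense eigen-solution of the normalized Laplacian, for comparison."""
    deg = W.sum(axis=1)
    dm12 = 1.0 / np.sqrt(deg)
    L = np.eye(len(W)) - dm12[:, None] * W * dm12[None, :]
    lam, vec = scipy.linalg.eigh(L)
    comp = dm12[:, None] * vec[:, 1 : n_components + 1]
    comp /= np.linalg.norm(comp, axis=0, keepdims=True)
    return lam, comp


class TestCosineAffinity:
    def test_identical_orthogonal_and_opposite_rows(self):
        aff = _affinity_from_rows([[1.0, 0], [1.0, 0], [0, 2.0], [-1.0, 0]])
        a = aff.values
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 2] == pytest.approx(0.0)      # orthogonal
        assert a[0, 3] == pytest.approx(0.0)      # cosine -1 clipped to 0
        np.testing.assert_allclose(np.diag(a), 1.0)

    def test_zero_row_named(self):
        fc = FCMatrix(values=np.array([[1.0, 0], [0.0, 0]]), sparsified=True)
        with pytest.raises(ValueError, match=r"\[1\]"):
            cosine_affinity(fc)

    def test_unsparsified_needs_override(self):
        fc = FCMatrix(values=np.eye(3))
        with pytest.raises(ValueError):
            cosine_affinity(fc)
        assert cosine_affinity(fc, allow_unsparsified=True).n_voxels == 3


class TestLaplacianEigenmaps:
    def test_path_graph_spectrum(self):
        # 3-node path: normalized-Laplacian spectrum {0, 1, 2}
        W = np.array([[0.0, 1, 0], [1, 0, 1], [0, 1, 0]])
        lam, _ = _dense_oracle(W, 1)
        np.testing.assert_allclose(lam, [0.0, 1.0, 2.0], atol=1e-12)
        gs = sg.laplacian_eigenmap(AffinityMatrix(values=W / W.max()), 1)
        assert gs.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)

    def test_complete_graph_flat_spectrum(self):
        n = 6
        W = np.ones((n, n)) - np.eye(n)
        # K_n nontrivial eigenvalues all n/(n-1); embedding degenerate but
        # returned in the documented ascending order
        gs = sg.laplacian_eigenmap(AffinityMatrix(values=W / W.max()), 3)
        np.testing.assert_allclose(gs.eigenvalues, n / (n - 1), atol=1e-10)

    @pytest.mark.parametrize("n", [30, 120, 200])
    def test_dense_oracle_equivalence(self, n):
        rng = np.random.default_rng(n)
        base = rng.uniform(0.05, 1.0, size=(n, n))
        W = 0.5 * (base + base.T)
        np.fill_diagonal(W, 0.0)
        gs = sg.laplacian_eigenmap(AffinityMatrix(values=W), 5)
        lam, comp = _dense_oracle(W, 5)
        np.testing.assert_allclose(gs.eigenvalues, lam[1:6], atol=1e-8)
        for j in range(5):
            dot = comp[:, j] @ gs.components[:, j]
            np.testing.assert_allclose(
                np.sign(dot) * comp[:, j], gs.components[:, j], atol=1e-8
            )

    def test_sparse_solver_matches_dense_oracle(self):
        n = 600  # above the dense threshold: exercises shift-invert Lanczos
        rng = np.random.default_rng(0)
        base = rng.uniform(0.05, 1.0, size=(n, n))
        W = 0.5 * (base + base.T)
        np.fill_diagonal(W, 0.0)
        gs = sg.laplacian_eigenmap(AffinityMatrix(values=W), 3)
        lam, comp = _dense_oracle(W, 3)
        np.testing.assert_allclose(gs.eigenvalues, lam[1:4], atol=1e-7)

    def test_disconnected_graph_rejected(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            sg.laplacian_eigenmap(AffinityMatrix(values=W), 1)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(0.1, 1.0, size=(40, 40))
        W = 0.5 * (base + base.T)
        np.fill_diagonal(W, 0.0)
        a = sg.laplacian_eigenmap(AffinityMatrix(values=W), 4)
        b = sg.laplacian_eigenmap(AffinityMatrix(values=0.3 * W), 4)
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, atol=1e-10)
        np.testing.assert_allclose(a.components, b.components, atol=1e-8)

    def test_recovers_planted_axis_end_to_end(self):
        g = sg.make_geometry((120, 1, 1), 7, seed=1, n_cortical_rois=40)
        c = sg.simulate_twin_cohort(1, 1, 0, 0, seed=1)
        ts = sg.simulate_timeseries(
            c, g, timepoints=200, coupling_strength=1.0, noise_sd=0.05,
            heritable_shift=0.0, seed=4,
        )
        fc = sg.fisher_z(sg.compute_fc(ts.voxel_ts[0], ts.roi_ts[0]))
        gs = sg.laplacian_eigenmap(
            cosine_affinity(sg.threshold_top_fraction(fc, 0.10)), 5
        )
        rho = spearmanr(gs.fg(1), g.hierarchy_axis).statistic
        assert abs(rho) >= 0.9


class TestVarianceExplained:
    def test_weighted_proportions(self):
        np.testing.assert_allclose(
            sg.variance_explained([0.2, 0.6]), [2 / 3, 1 / 3]
        )

    def test_flat_spectrum_equal_shares(self):
        np.testing.assert_allclose(
            sg.variance_explained([0.5, 0.5, 0.5]), [1 / 3] * 3
        )

    def test_sums_to_one_and_non_increasing(self):
        p = sg.variance_explained([0.1, 0.3, 0.8, 0.95])
        assert p.sum() == pytest.approx(1.0)
        assert np.all(np.diff(p) <= 0)

    def test_degenerate_spectrum_rejected(self):
        with pytest.raises(ValueError):
            sg.variance_explained([1.2, 1.5])


class TestProcrustes:
    def _reference(self, n=50, k=4, seed=0):
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.standard_normal((n, k)))
        return sg.GradientSet(
            components=q, eigenvalues=np.linspace(0.1, 0.4, k),
            variance_explained=np.full(k, 1 / k),
        )

    def test_self_alignment_is_identity(self):
        ref = self._reference()
        out = sg.procrustes_align(ref, ref)
        assert np.linalg.norm(out.components - ref.components) < 1e-10
        assert out.aligned_to == "group"

    def test_recovers_random_orthogonal_transform(self):
        ref = self._reference(seed=1)
        rng = np.random.default_rng(2)
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        rotated = sg.GradientSet(
            components=ref.components @ Q,
            eigenvalues=ref.eigenvalues,
            variance_explained=ref.variance_explained,
        )
        out = sg.procrustes_align(rotated, ref)
        assert np.linalg.norm(out.components - ref.components) < 1e-8

    def test_restores_sign_flip(self):
        ref = self._reference(seed=3)
        flipped = ref.components.copy()
        flipped[:, 0] *= -1
        out = sg.procrustes_align(
            sg.GradientSet(flipped, ref.eigenvalues, ref.variance_explained), ref
        )
        assert np.linalg.norm(out.components - ref.components) < 1e-10

    def test_orthonormal_columns_keep_their_norms(self):
        ref = self._reference(seed=4)
        rng = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        out = sg.procrustes_align(
            sg.GradientSet(ref.components @ Q, ref.eigenvalues,
                           ref.variance_explained),
            ref,
        )
        norms = np.linalg.norm(out.components, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)

    def test_shape_mismatch_rejected(self):
        ref = self._reference()
        bad = sg.GradientSet(
            components=ref.components[:, :2],
            eigenvalues=ref.eigenvalues[:2],
            variance_explained=ref.variance_explained[:2],
        )
        with pytest.raises(ValueError):
            sg.procrustes_align(bad, ref)


def test_orient_to_axis_makes_correlation_positive():
    rng = np.random.default_rng(6)
    coord = np.arange(30.0)
    comp = np.c_[-coord + rng.normal(0, 0.1, 30), rng.standard_normal(30)]
    gs = sg.GradientSet(comp, np.array([0.1, 0.2]), np.array([0.6, 0.4]))
    out = orient_to_axis(gs, coord)
    assert spearmanr(out.fg(1), coord).statistic > 0
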