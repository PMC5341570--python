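"""Covariance PCA, projections, DCCM and subspace overlaps."""

import numpy as np
import pytest

from conftest import point_trajectory
from rindyn.covariance import (
    PCAResult,
    build_pca,
    dccm,
    porcupine_export,
    project,
    subspace_overlap,
)
from rindyn.synth import GaussianTrajSpec, gen_gaussian_traj


def _planted_traj(n_atoms=10, variances=(1.0,), noise=0.01, n_frames=2000,
                  seed=0):
    rng = np.random.default_rng(seed)
    ref = rng.standard_normal((n_atoms, 3))
    k = len(variances)
    raw = rng.standard_normal((k, 3 * n_atoms))
    modes, _ = np.linalg.qr(raw.T)
    modes = modes.T[:k]
    spec = GaussianTrajSpec(reference=ref, modes=modes,
                            mode_variances=np.array(variances),
                            noise_variance=noise, n_frames=n_frames,
                            seed=seed + 1)
    return gen_gaussian_traj(spec), modes


class TestBuildPca:
    def test_planted_mode_recovery(self):
        traj, modes = _planted_traj()
        pca = build_pca(traj, np.arange(10), superpose=False)
        assert abs(pca.eigenvectors[0] @ modes[0]) > 0.99
        share = 1.0 / (1.0 + 0.01 * 30)  # planted variance / total
        assert pca.variance_fractions[0] == pytest.approx(share, rel=0.1)

    def test_two_mode_recovery_and_ordering(self):
        traj, modes = _planted_traj(variances=(2.0, 0.5), noise=0.005,
                                    n_frames=4000, seed=3)
        pca = build_pca(traj, np.arange(10), superpose=False)
        assert abs(pca.eigenvectors[0] @ modes[0]) > 0.98
        assert abs(pca.eigenvectors[1] @ modes[1]) > 0.98
        assert pca.eigenvalues[0] > pca.eigenvalues[1]

    def test_static_trajectory_all_zero(self):
        coords = np.repeat(np.random.default_rng(0).standard_normal((1, 5, 3)),
                           4, axis=0)
        pca = build_pca(point_trajectory(coords), np.arange(5))
        assert np.allclose(pca.eigenvalues, 0.0, atol=1e-12)

    def test_trace_conservation_and_orthonormality(self):
        traj, _ = _planted_traj(seed=5)
        pca = build_pca(traj, np.arange(10), superpose=False)
        dev = traj.coordinates.reshape(traj.n_frames, -1)
        dev = dev - dev.mean(axis=0)
        cov_trace = (dev ** 2).sum() / traj.n_frames
        assert pca.eigenvalues.sum() == pytest.approx(cov_trace, rel=1e-8)
        assert pca.variance_fractions.sum() == pytest.approx(1.0, abs=1e-8)
        gram = pca.eigenvectors @ pca.eigenvectors.T
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        assert np.all(pca.eigenvalues >= -1e-10)


class TestProject:
    def test_mean_structure_projects_to_zero(self):
        traj, _ = _planted_traj(seed=7)
        pca = build_pca(traj, np.arange(10))
        mean_traj = point_trajectory(pca.mean[None])
        proj = project(mean_traj, pca, 3)
        assert np.allclose(proj, 0.0, atol=1e-8)

    def test_projection_variance_matches_eigenvalues(self):
        traj, _ = _planted_traj(seed=8, n_frames=3000)
        pca = build_pca(traj, np.arange(10))
        proj = project(traj, pca, 3)
        for j in range(3):
            assert proj[:, j].var() == pytest.approx(pca.eigenvalues[j], rel=0.05)

    def test_projections_uncorrelated(self):
        traj, _ = _planted_traj(variances=(1.0, 0.3), seed=9, n_frames=2000)
        pca = build_pca(traj, np.arange(10))
        proj = project(traj, pca, 2)
        r = np.corrcoef(proj[:, 0], proj[:, 1])[0, 1]
        assert abs(r) < 0.05


class TestDccm:
    def test_collective_translation_fully_correlated(self):
        rng = np.random.default_rng(10)
        base = rng.standard_normal((4, 3))
        shifts = rng.standard_normal((50, 1, 3))
        coords = base[None] + shifts
        mat = dccm(point_trajectory(coords), np.arange(4), superpose=False).matrix
        assert np.allclose(mat, 1.0, atol=1e-10)

    def test_independent_groups_uncorrelated(self):
        rng = np.random.default_rng(11)
        n = 5000
        coords = np.zeros((n, 6, 3))
        coords[:, :3, :] = rng.standard_normal((n, 1, 3)) * 0.3
        coords[:, 3:, :] = rng.standard_normal((n, 1, 3)) * 0.3
        coords += rng.standard_normal((n, 6, 3)) * 0.01
        mat = dccm(point_trajectory(coords), np.arange(6), superpose=False).matrix
        inter = mat[:3, 3:]
        assert np.abs(inter).max() < 0.1

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(12)
        coords = rng.standard_normal((30, 5, 3)) * 0.1
        mat = dccm(point_trajectory(coords), np.arange(5), superpose=False).matrix
        dev = coords - coords.mean(axis=0)
        brute = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                num = np.mean(np.einsum("fd,fd->f", dev[:, i], dev[:, j]))
                den = np.sqrt(np.mean((dev[:, i] ** 2).sum(axis=1))
                              * np.mean((dev[:, j] ** 2).sum(axis=1)))
                brute[i, j] = num / den
        assert np.allclose(mat, brute, atol=1e-10)

    def test_symmetry_unit_diagonal_bounds(self):
        rng = np.random.default_rng(13)
        coords = rng.standard_normal((100, 6, 3))
        mat = dccm(point_trajectory(coords), np.arange(6)).matrix
        assert np.allclose(mat, mat.T, atol=1e-12)
        assert np.allclose(np.diag(mat), 1.0, atol=1e-12)
        assert np.all(np.abs(mat) <= 1.0 + 1e-12)


def _pca_from_basis(evecs, evals, mean=None):
    evals = np.asarray(evals, dtype=float)
    fractions = evals / evals.sum() if evals.sum() > 0 else np.zeros_like(evals)
    n_sel = evecs.shape[1] // 3
    return PCAResult(eigenvalues=evals, eigenvectors=evecs,
                     variance_fractions=fractions,
                     mean=np.zeros((n_sel, 3)) if mean is None else mean,
                     selection=np.arange(n_sel))


class TestSubspaceOverlap:
    def test_self_overlap_is_unity(self):
        traj, _ = _planted_traj(seed=14)
        pca = build_pca(traj, np.arange(10))
        report = subspace_overlap(pca, pca, k=10)
        assert report.rmsip == pytest.approx(1.0, abs=1e-8)
        assert report.covariance_overlap == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(report.per_vector, 1.0, atol=1e-8)

    def test_orthogonal_complement_zero_rmsip(self):
        eye = np.eye(12)
        a = _pca_from_basis(eye[:3], [1.0, 1.0, 1.0])
        b = _pca_from_basis(eye[3:6], [1.0, 1.0, 1.0])
        report = subspace_overlap(a, b, k=3)
        assert report.rmsip == pytest.approx(0.0, abs=1e-12)

    def test_rmsip_matches_bruteforce_and_mixing_invariance(self):
        rng = np.random.default_rng(15)
        basis, _ = np.linalg.qr(rng.standard_normal((12, 12)))
        a = _pca_from_basis(basis.T[:4], np.ones(4))
        # mix the same subspace by an orthogonal 4x4
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        b = _pca_from_basis(q @ basis.T[:4], np.ones(4))
        report = subspace_overlap(a, b, k=4)
        brute = np.sqrt(sum((a.eigenvectors[i] @ b.eigenvectors[j]) ** 2
                            for i in range(4) for j in range(4)) / 4)
        assert report.rmsip == pytest.approx(brute, abs=1e-12)
        assert report.rmsip == pytest.approx(1.0, abs=1e-10)  # same subspace

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(16)
        basis, _ = np.linalg.qr(rng.standard_normal((9, 9)))
        a = _pca_from_basis(basis.T[:3], [2.0, 1.0, 0.5])
        b = _pca_from_basis(-basis.T[:3], [2.0, 1.0, 0.5])
        report = subspace_overlap(a, b, k=3)
        assert report.rmsip == pytest.approx(1.0, abs=1e-10)
        assert report.covariance_overlap == pytest.approx(1.0, abs=1e-10)


class TestPorcupine:
    def test_zero_eigenvector_gives_null_arrows(self):
        evecs = np.zeros((1, 9))
        pca = _pca_from_basis(evecs, [0.0])
        table = porcupine_export(pca, 0, 2.0)
        assert np.allclose(table[:, 1:4], table[:, 4:7])

    def test_arrow_lengths_proportional_to_mode_norm(self):
        rng = np.random.default_rng(17)
        vec = rng.standard_normal(9)
        vec /= np.linalg.norm(vec)
        pca = _pca_from_basis(vec[None], [1.0])
        table = porcupine_export(pca, 0, 3.0)
        lengths = np.linalg.norm(table[:, 4:7] - table[:, 1:4], axis=1)
        per_atom = np.linalg.norm(vec.reshape(3, 3), axis=1)
        assert np.allclose(lengths, 3.0 * per_atom, atol=1e-12)

    def test_planted_mode_arrows_align_with_displacement(self):
        traj, modes = _planted_traj(noise=0.001, seed=18)
        pca = build_pca(traj, np.arange(10), superpose=False)
        table = porcupine_export(pca, 0, 1.0)
        arrows = (table[:, 4:7] - table[:, 1:4]).reshape(-1)
        mode = modes[0]
        cos = abs(arrows @ mode) / np.linalg.norm(arrows)
        assert cos > 0.95
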