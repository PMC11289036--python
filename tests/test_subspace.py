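"""SVD of cohort spectra, k-selection, and the η projection diagnostic."""

import numpy as np
import pytest

from mousedyn.spectral import Spectrum
from mousedyn.subspace import (
    ReferenceSubspace, build_matrix, choose_k, cumulative_variance, eta,
    fit_reference_subspace, load_subspace, save_subspace, svd,
)


def make_spectrum(Z, pid="p", dt=20.0):
    N = len(Z)
    f = np.arange(-N // 2, N // 2) / (N * dt * 1e-3)
    return Spectrum(participant_id=pid, Z=np.asarray(Z, complex), f=f, N=N, dt=dt)


def random_subspace(rng, N, k):
    Q, _ = np.linalg.qr(rng.standard_normal((N, k))
                        + 1j * rng.standard_normal((N, k)))
    sub = ReferenceSubspace(U_tilde=Q[:, :k], k=k, variance_fraction=1.0,
                            threshold=0.5, N=N, dt=20.0, provenance="test")
    return sub


def eta_least_squares_oracle(basis, Z):
    """η via an independent normal-equations solve of min ||B c - Z||."""
    B = basis
    c = np.linalg.solve(B.conj().T @ B, B.conj().T @ Z)
    return np.linalg.norm(B @ c) / np.linalg.norm(Z)


class TestBuildMatrix:
    def test_shape_and_order(self):
        rng = np.random.default_rng(0)
        specs = [make_spectrum(rng.standard_normal(8) + 0j, pid=f"p{i}")
                 for i in range(2)]
        mat = build_matrix(specs)
        assert mat.A.shape == (8, 2)
        assert mat.participant_ids == ["p0", "p1"]

    def test_column_retrieval_exact(self):
        rng = np.random.default_rng(1)
        specs = [make_spectrum(rng.standard_normal(8)
                               + 1j * rng.standard_normal(8), pid=f"p{i}")
                 for i in range(3)]
        mat = build_matrix(specs)
        assert np.array_equal(mat.column("p1"), specs[1].Z)

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            build_matrix([make_spectrum(np.ones(8)), make_spectrum(np.ones(10))])

    def test_cohort_not_smaller_than_spectrum_error(self):
        specs = [make_spectrum(np.random.default_rng(i).standard_normal(4) + 0j,
                               pid=str(i)) for i in range(4)]
        with pytest.raises(ValueError):
            build_matrix(specs)


class TestSvd:
    def test_orthogonal_columns_give_their_norms(self):
        A = np.zeros((8, 2), complex)
        A[0, 0], A[1, 1] = 3.0, 2.0
        specs = [make_spectrum(A[:, j], pid=str(j)) for j in range(2)]
        res = svd(build_matrix(specs))
        assert np.allclose(res.s, [3.0, 2.0])

    def test_rank_one(self):
        rng = np.random.default_rng(2)
        u = rng.standard_normal(16) + 1j * rng.standard_normal(16)
        u /= np.linalg.norm(u)
        v = rng.standard_normal(3) + 1j * rng.standard_normal(3)
        v /= np.linalg.norm(v)
        A = 5.0 * np.outer(u, v.conj())
        specs = [make_spectrum(A[:, j], pid=str(j)) for j in range(3)]
        res = svd(build_matrix(specs))
        assert abs(res.s[0] - 5.0) < 1e-10
        assert res.s[1] <= 1e-10 * 5.0

    def test_singular_values_match_eigen_oracle(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((32, 6)) + 1j * rng.standard_normal((32, 6))
        specs = [make_spectrum(A[:, j], pid=str(j)) for j in range(6)]
        res = svd(build_matrix(specs))
        eigvals = np.linalg.eigvalsh(A.conj().T @ A)[::-1]
        assert np.allclose(res.s, np.sqrt(np.clip(eigvals, 0, None)), rtol=1e-8)

    def test_reconstruction_and_orthonormality(self):
        rng = np.random.default_rng(4)
        A = rng.standard_normal((20, 5)) + 1j * rng.standard_normal((20, 5))
        specs = [make_spectrum(A[:, j], pid=str(j)) for j in range(5)]
        res = svd(build_matrix(specs))
        recon = res.U @ np.diag(res.s) @ res.V.conj().T
        assert np.linalg.norm(recon - A) / np.linalg.norm(A) < 1e-8
        assert np.allclose(res.U.conj().T @ res.U, np.eye(5), atol=1e-8)
        assert np.allclose(res.V.conj().T @ res.V, np.eye(5), atol=1e-8)


class TestVarianceAndK:
    def _res_with_s(self, s):
        class R:
            pass
        r = R()
        r.s = np.asarray(s, float)
        return r

    def test_fractions(self):
        fr = cumulative_variance(self._res_with_s([2.0, 1.0]))
        assert np.allclose(fr, [0.8, 1.0])
        fr = cumulative_variance(self._res_with_s([1.0, 0.0, 0.0]))
        assert np.allclose(fr, [1.0, 1.0, 1.0])

    def test_monotone(self):
        rng = np.random.default_rng(5)
        fr = cumulative_variance(self._res_with_s(np.sort(rng.uniform(
            0.1, 5.0, size=12))[::-1]))
        assert np.all(np.diff(fr) >= -1e-15)
        assert abs(fr[-1] - 1.0) < 1e-12

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            cumulative_variance(self._res_with_s([0.0, 0.0]))

    def test_choose_k_first_crossing(self):
        assert choose_k(np.array([0.3, 0.45, 0.55]), 0.5) == 3
        assert choose_k(np.array([0.6, 0.9, 1.0]), 0.5) == 1
        assert choose_k(np.array([0.3, 0.45, 0.55, 1.0]), 1.0) == 4


class TestFitReferenceSubspace:
    def test_identical_spectra_rank_one(self):
        rng = np.random.default_rng(6)
        Z = rng.standard_normal(16) + 1j * rng.standard_normal(16)
        specs = [make_spectrum(Z, pid=str(i)) for i in range(3)]
        sub = fit_reference_subspace(specs, threshold=0.5)
        assert sub.k == 1
        assert eta(sub, make_spectrum(Z)).eta > 1 - 1e-10

    def test_planted_basis_recovery(self):
        rng = np.random.default_rng(7)
        N, k_true, P = 64, 4, 12
        Q, _ = np.linalg.qr(rng.standard_normal((N, k_true))
                            + 1j * rng.standard_normal((N, k_true)))
        specs = []
        for i in range(P):
            c = rng.standard_normal(k_true) + 1j * rng.standard_normal(k_true)
            v = Q @ c
            v += 1e-8 * (rng.standard_normal(N) + 1j * rng.standard_normal(N))
            specs.append(make_spectrum(v, pid=str(i)))
        sub = fit_reference_subspace(specs, threshold=0.5)
        assert sub.k <= k_true
        # principal angles between span(U_tilde) and the planted span
        sv = np.linalg.svd(Q.conj().T @ sub.U_tilde, compute_uv=False)
        angles = np.arccos(np.clip(sv, -1, 1))
        assert np.max(angles) < 1e-3

    def test_provenance_changes_with_threshold(self):
        rng = np.random.default_rng(8)
        specs = [make_spectrum(rng.standard_normal(16)
                               + 1j * rng.standard_normal(16), pid=str(i))
                 for i in range(5)]
        a = fit_reference_subspace(specs, threshold=0.5)
        b = fit_reference_subspace(specs, threshold=0.6)
        assert a.provenance != b.provenance

    def test_columns_orthonormal(self):
        rng = np.random.default_rng(9)
        specs = [make_spectrum(rng.standard_normal(32)
                               + 1j * rng.standard_normal(32), pid=str(i))
                 for i in range(8)]
        sub = fit_reference_subspace(specs, threshold=0.9)
        G = sub.U_tilde.conj().T @ sub.U_tilde
        assert np.allclose(G, np.eye(sub.k), atol=1e-8)


class TestEta:
    def test_in_span_is_one(self):
        sub = random_subspace(np.random.default_rng(10), 16, 3)
        score = eta(sub, 3.0 * sub.U_tilde[:, 0], participant_id="x")
        assert abs(score.eta - 1.0) < 1e-10

    def test_orthogonal_is_zero(self):
        rng = np.random.default_rng(11)
        sub = random_subspace(rng, 16, 3)
        g = rng.standard_normal(16) + 1j * rng.standard_normal(16)
        g -= sub.U_tilde @ (sub.U_tilde.conj().T @ g)
        assert eta(sub, g).eta < 1e-10

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(12)
        sub = random_subspace(rng, 6, 2)
        for _ in range(20):
            Z = rng.standard_normal(6) + 1j * rng.standard_normal(6)
            expected = eta_least_squares_oracle(sub.U_tilde, Z)
            assert abs(eta(sub, Z).eta - expected) < 1e-10

    def test_scale_invariance(self):
        rng = np.random.default_rng(13)
        sub = random_subspace(rng, 16, 4)
        Z = rng.standard_normal(16) + 1j * rng.standard_normal(16)
        base = eta(sub, Z).eta
        for c in (2.0, -3.5, 1j, 0.1 - 7j):
            assert abs(eta(sub, c * Z).eta - base) < 1e-10

    def test_monotone_in_k(self):
        rng = np.random.default_rng(14)
        specs = [make_spectrum(rng.standard_normal(32)
                               + 1j * rng.standard_normal(32), pid=str(i))
                 for i in range(10)]
        Z = rng.standard_normal(32) + 1j * rng.standard_normal(32)
        vals = [eta(fit_reference_subspace(specs, k=k), Z).eta
                for k in range(1, 11)]
        assert np.all(np.diff(vals) >= -1e-12)

    def test_expected_eta_squared_is_k_over_N(self):
        rng = np.random.default_rng(15)
        N, k, n_draws = 64, 8, 10_000
        sub = random_subspace(rng, N, k)
        G = (rng.standard_normal((n_draws, N))
             + 1j * rng.standard_normal((n_draws, N)))
        proj = G @ sub.U_tilde.conj()
        e2 = (np.linalg.norm(proj, axis=1) / np.linalg.norm(G, axis=1)) ** 2
        assert abs(e2.mean() - k / N) < 0.01

    def test_zero_spectrum_error(self):
        sub = random_subspace(np.random.default_rng(16), 8, 2)
        with pytest.raises(ValueError):
            eta(sub, np.zeros(8, complex))

    def test_length_mismatch_error(self):
        sub = random_subspace(np.random.default_rng(17), 8, 2)
        with pytest.raises(ValueError):
            eta(sub, np.ones(10, complex))


def test_subspace_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(18)
    specs = [make_spectrum(rng.standard_normal(16)
                           + 1j * rng.standard_normal(16), pid=str(i))
             for i in range(5)]
    sub = fit_reference_subspace(specs, threshold=0.6)
    path = tmp_path / "ref.npz"
    save_subspace(sub, path)
    back = load_subspace(path)
    assert back.k == sub.k and back.provenance == sub.provenance
    assert np.array_equal(back.U_tilde, sub.U_tilde)
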