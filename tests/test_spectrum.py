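"""Reduced-matrix covariance spectra, participation ratio, limiting regimes."""

import numpy as np
import pytest

import lowrank_rnn as lr
from conftest import random_stable_spec


def _dense_eig(sigma):
    evals, evecs = np.linalg.eigh(sigma)
    order = np.argsort(-evals)
    return evals[order], evecs[:, order]


class TestReducedMatrix:
    def test_single_unit_pair(self):
        m = lr.orthonormal_scaffold(10, 1, 0)[0]
        np.testing.assert_allclose(lr.reduced_matrix([(m, m)]), [[1.0]], atol=1e-14)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            lr.reduced_matrix([])

    def test_random_low_rank_matches_dense(self):
        rng = np.random.default_rng(1)
        lefts = rng.standard_normal((3, 12))
        rights = rng.standard_normal((3, 12))
        m_full = sum(np.outer(l, r) for l, r in zip(lefts, rights))
        red = lr.reduced_matrix(list(zip(lefts, rights)))
        dense = np.linalg.eigvals(m_full)
        dense = np.sort_complex(dense[np.argsort(-np.abs(dense))][:3])
        np.testing.assert_allclose(
            np.sort_complex(np.linalg.eigvals(red)), dense, atol=1e-10
        )

    def test_one_d_covariance_factor_pairs_reproduce_eigenvalues(self):
        # the rank-two structure of the 1-D-input covariance collapses to a
        # 2x2 reduced matrix whose eigenvalues are mu_+-
        spec = lr.build_rank_one(30, 2.0, 0.3, seed=3)
        u = lr.orthonormal_scaffold(30, 3, 9)[2]
        ens = lr.make_input(30, "one_d", u=u)
        cov = lr.stationary_covariance(spec, ens)
        m = spec.m_vectors[0]
        geom = lr.input_geometry(ens, spec)
        rho_nu = geom.rho_nu[0, 0]
        lam = spec.eigenvalues[0]
        alpha = spec.k / (2 - lam)
        beta = spec.k**2 / ((2 - lam) * (1 - lam))
        pairs = [
            (u, 0.5 * (u + alpha * rho_nu * m)),
            (m, 0.5 * (alpha * rho_nu * u + beta * rho_nu**2 * m)),
        ]
        red = lr.reduced_matrix(pairs)
        approx = np.sort(np.linalg.eigvals(red).real)
        dense = np.sort(np.linalg.eigvalsh(cov.sigma))[-2:]
        np.testing.assert_allclose(approx, dense, atol=1e-10)


class TestSpectrum1D:
    def test_disengaged_recurrence(self):
        # rho_nu = 0: one-dimensional activity fully along u
        z = lr.orthonormal_scaffold(40, 3, 2)
        spec = lr.ConnectivitySpec(k=2.0, m_vectors=z[:1], n_vectors=z[1:2])
        ens = lr.make_input(40, "one_d", u=z[2])
        summ = lr.spectrum_1d(spec, ens)
        assert summ.mu_plus == pytest.approx(0.5, abs=1e-12)
        assert summ.mu_minus == pytest.approx(0.0, abs=1e-12)
        assert summ.gamma_plus == 0.0
        np.testing.assert_allclose(summ.v_plus, z[2], atol=1e-12)
        assert summ.participation_ratio == pytest.approx(1.0, abs=1e-12)

    def test_input_along_n_frozen_values(self):
        # dense-eigensolve oracle gave (3 +- sqrt(5))/4 and D = 9/7
        spec = lr.build_rank_one(50, 2.0, 0.0, seed=2)
        ens = lr.make_input(50, "one_d", u=spec.n_vectors[0])
        summ = lr.spectrum_1d(spec, ens)
        assert summ.mu_plus == pytest.approx((3 + np.sqrt(5)) / 4, abs=1e-12)
        assert summ.mu_minus == pytest.approx((3 - np.sqrt(5)) / 4, abs=1e-12)
        assert summ.participation_ratio == pytest.approx(9.0 / 7.0, abs=1e-12)
        assert lr.closed_form_D_1d(spec, ens) == pytest.approx(9.0 / 7.0, abs=1e-12)

    def test_eigenpairs_satisfy_eigen_equation(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            spec = random_stable_spec(rng, N=30, rank=1)
            ens = lr.make_input(30, "one_d", seed=int(rng.integers(2**31)))
            cov = lr.stationary_covariance(spec, ens)
            summ = lr.spectrum_1d(spec, ens)
            for mu, v in ((summ.mu_plus, summ.v_plus), (summ.mu_minus, summ.v_minus)):
                np.testing.assert_allclose(cov.sigma @ v, mu * v, atol=1e-9)

    def test_wrong_regime_errors(self, rank_one_spec, rank_two_spec):
        with pytest.raises(lr.WrongRegimeError):
            lr.spectrum_1d(rank_two_spec, lr.make_input(40, "one_d", seed=0))
        with pytest.raises(lr.WrongRegimeError):
            lr.spectrum_1d(rank_one_spec, lr.make_input(8, "high_d"))

    def test_sign_convention_overlap_with_u_nonnegative(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            spec = random_stable_spec(rng, N=25, rank=1)
            ens = lr.make_input(25, "one_d", seed=int(rng.integers(2**31)))
            summ = lr.spectrum_1d(spec, ens)
            assert summ.v_plus @ ens.u >= 0
            assert summ.v_minus @ ens.u >= 0


class TestSpectrumHD:
    def test_zero_overlap_frozen_values(self):
        spec = lr.build_rank_one(50, 2.0, 0.0, seed=2)
        summ = lr.spectrum_hd(spec)
        assert summ.mu_plus == pytest.approx((2 + np.sqrt(2)) / 2, abs=1e-12)
        assert summ.mu_minus == pytest.approx((2 - np.sqrt(2)) / 2, abs=1e-12)
        assert summ.gamma_plus == pytest.approx(1 + np.sqrt(2), abs=1e-12)
        assert summ.gamma_minus == pytest.approx(1 - np.sqrt(2), abs=1e-12)
        assert np.sum(summ.classes == "reference") == 48

    def test_reference_bracketing_strict_for_positive_coupling(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            spec = random_stable_spec(rng, N=30, rank=1)
            summ = lr.spectrum_hd(spec)
            assert summ.mu_plus > 0.5 > summ.mu_minus

    def test_symmetric_limit_mu_minus_approaches_half(self):
        spec = lr.build_rank_one(30, 2.0, 0.5 - 1e-6, seed=1)  # rho -> 1/k
        summ = lr.spectrum_hd(spec)
        assert summ.mu_minus == pytest.approx(0.5, abs=1e-5)
        assert summ.mu_plus > 1e3

    def test_antisymmetric_limit_values(self):
        k = 2.0
        spec = lr.build_rank_one(30, k, -1.0, seed=1)
        summ = lr.spectrum_hd(spec)
        assert summ.gamma_plus == pytest.approx(1.0, abs=1e-12)
        assert summ.mu_plus == pytest.approx(0.5, abs=1e-12)
        assert summ.mu_minus == pytest.approx(1.0 / (2 * (1 + k)), abs=1e-12)
        assert summ.gamma_minus == pytest.approx(-1.0 / (1 + k), abs=1e-12)

    def test_eigenpairs_satisfy_eigen_equation(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            spec = random_stable_spec(rng, N=30, rank=1)
            cov = lr.stationary_covariance(spec, lr.make_input(30, "high_d"))
            summ = lr.spectrum_hd(spec)
            for mu, v in ((summ.mu_plus, summ.v_plus), (summ.mu_minus, summ.v_minus)):
                np.testing.assert_allclose(cov.sigma @ v, mu * v, atol=1e-9)

    @pytest.mark.parametrize("rho", [0.0, -0.5, -0.9])
    def test_monotonicity_in_coupling(self, rho):
        # mu_+ grows and mu_- shrinks with k at fixed non-positive overlap
        # (for rho_mn > 0, mu_- is non-monotone: it returns to 1/2 as
        # lambda -> 1, so the check is restricted to rho_mn <= 0)
        mu_p, mu_m = lr.eigenvalues_hd(np.linspace(0.1, 3.0, 25), rho)
        assert np.all(np.diff(mu_p) > 0)
        assert np.all(np.diff(mu_m) < 0)


class TestSpectrumRankR:
    def test_orthogonal_parametrization_counts(self, rank_two_spec):
        summ = lr.spectrum_rank_r_hd(rank_two_spec)
        assert np.atleast_1d(summ.mu_plus).size == 2
        assert np.atleast_1d(summ.mu_minus).size == 2

    def test_orthogonal_blocks_match_rank_one_formula(self, rank_two_spec):
        # each rank-one component contributes its own (mu_+, mu_-) pair
        summ = lr.spectrum_rank_r_hd(rank_two_spec)
        got = np.sort(np.concatenate([np.atleast_1d(summ.mu_plus), np.atleast_1d(summ.mu_minus)]))
        expected = []
        for rho in np.diag(rank_two_spec.rho_mn):
            p, m = lr.eigenvalues_hd(rank_two_spec.k, float(rho))
            expected += [float(p), float(m)]
        np.testing.assert_allclose(got, np.sort(expected), atol=1e-10)

    def test_block_reduced_matches_dense_eigensolve(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            spec = random_stable_spec(rng, N=40, rank=2)
            cov = lr.stationary_covariance(spec, lr.make_input(40, "high_d"))
            summ = lr.spectrum_rank_r_hd(spec)
            dense = np.sort(np.linalg.eigvalsh(cov.sigma))
            got = np.sort(summ.eigenvalues)
            np.testing.assert_allclose(got, dense, atol=1e-9)

    def test_cross_parametrization_decouples_to_zero_lambda_pairs(self):
        spec = lr.build_low_rank(40, 2.0, rho_m1m2=0.0, rho_n1n2=0.0, seed=13)
        summ = lr.spectrum_rank_r_hd(spec)
        p, m = (float(x) for x in lr.eigenvalues_hd(2.0, 0.0))
        np.testing.assert_allclose(np.sort(np.atleast_1d(summ.mu_plus)), [p, p], atol=1e-10)
        np.testing.assert_allclose(np.sort(np.atleast_1d(summ.mu_minus)), [m, m], atol=1e-10)

    def test_perturbed_count_at_most_2r(self):
        rng = np.random.default_rng(33)
        for rank in (1, 2):
            for _ in range(10):
                spec = random_stable_spec(rng, N=30, rank=rank)
                summ = lr.spectrum_rank_r_hd(spec)
                n_pert = np.sum(summ.classes != "reference")
                assert n_pert <= 2 * rank
                if np.all(np.abs(spec.eigenvalues) > 1e-6):
                    assert n_pert == 2 * rank

    def test_perturbed_eigenvectors_satisfy_eigen_equation(self, rank_two_spec):
        cov = lr.stationary_covariance(rank_two_spec, lr.make_input(40, "high_d"))
        summ = lr.spectrum_rank_r_hd(rank_two_spec)
        mu_top = float(np.max(summ.eigenvalues))
        np.testing.assert_allclose(
            cov.sigma @ summ.v_plus, mu_top * summ.v_plus, atol=1e-9
        )


class TestParticipationRatio:
    def test_flat_spectrum_counts_dimensions(self):
        assert lr.participation_ratio(np.full(7, 0.3)) == pytest.approx(7.0)

    def test_single_mode(self):
        assert lr.participation_ratio([2.0, 0.0, 0.0]) == pytest.approx(1.0)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            lr.participation_ratio(np.zeros(5))

    def test_closed_form_matches_spectral_definition(self):
        # Eq-level identity: closed-form D == PR of the analytic eigenvalue pair
        rng = np.random.default_rng(2)
        vecs = rng.standard_normal((500, 3, 30))
        vecs /= np.linalg.norm(vecs, axis=2, keepdims=True)
        rho_mn = np.einsum("ij,ij->i", vecs[:, 0], vecs[:, 1])
        rho_nu = np.einsum("ij,ij->i", vecs[:, 1], vecs[:, 2])
        rho_mu = np.einsum("ij,ij->i", vecs[:, 0], vecs[:, 2])
        k = np.minimum(rng.uniform(0.2, 3.0, 500), 0.95 / np.maximum(rho_mn, 1e-9))
        d_closed = lr.participation_ratio_1d(k, rho_mn, rho_nu, rho_mu)
        mu_p, mu_m = lr.eigenvalues_1d(k, rho_mn, rho_nu, rho_mu)
        d_spec = (mu_p + mu_m) ** 2 / (mu_p**2 + mu_m**2)
        np.testing.assert_allclose(d_closed, d_spec, atol=1e-12)
        assert np.all(d_closed <= 2.0 + 1e-12)
        assert np.all(d_closed >= 1.0 - 1e-12)

    def test_closed_form_matches_dense_covariance_spectrum(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            spec = random_stable_spec(rng, N=25, rank=1)
            ens = lr.make_input(25, "one_d", seed=int(rng.integers(2**31)))
            cov = lr.stationary_covariance(spec, ens)
            dense = np.linalg.eigvalsh(cov.sigma)
            d_dense = lr.participation_ratio(np.maximum(dense, 0.0))
            assert lr.closed_form_D_1d(spec, ens) == pytest.approx(d_dense, abs=1e-9)


class TestOracleEquivalence:
    def test_closed_form_eigenpairs_match_dense_eigensolve(self):
        # >= 200 random stable specs across ranks and input regimes
        rng = np.random.default_rng(99)
        checked = 0
        while checked < 200:
            rank = 1 if checked % 2 == 0 else 2
            n_units = int(rng.integers(10, 61))
            if n_units < 2 * rank + 2:
                continue
            spec = random_stable_spec(rng, N=n_units, rank=rank)
            if rank == 1 and checked % 4 == 0:
                ens = lr.make_input(n_units, "one_d", seed=int(rng.integers(2**31)))
                cov = lr.stationary_covariance(spec, ens)
                summ = lr.spectrum_1d(spec, ens)
            else:
                cov = lr.stationary_covariance(spec, lr.make_input(n_units, "high_d"))
                summ = lr.spectrum_hd(spec) if rank == 1 else lr.spectrum_rank_r_hd(spec)
            dense_vals, dense_vecs = _dense_eig(cov.sigma)
            np.testing.assert_allclose(summ.eigenvalues, dense_vals, atol=1e-9)
            if summ.v_plus is not None and dense_vals[0] - dense_vals[1] > 1e-6:
                assert abs(summ.v_plus @ dense_vecs[:, 0]) > 1 - 1e-8
            checked += 1


class TestLimits:
    def test_symmetric_regime(self, rank_one_spec):
        lim = lr.limit_eigenvalues(rank_one_spec, "symmetric")
        assert lim.mu_minus == 0.5
        assert np.isinf(lim.mu_plus) and np.isinf(lim.gamma_plus)
        assert lim.gamma_minus == 0.0

    def test_antisymmetric_regime_values(self):
        spec = lr.build_rank_one(20, 2.0, -0.5, seed=0)
        lim = lr.limit_eigenvalues(spec, "antisymmetric")
        assert lim.gamma_plus == 1.0
        assert lim.gamma_minus == pytest.approx(-1.0 / 3.0)
        assert lim.mu_minus == pytest.approx(1.0 / 6.0)

    def test_antisymmetric_mu_minus_vanishes_at_strong_coupling(self):
        spec = lr.build_rank_one(20, 1e6, -0.5, seed=0)
        assert lr.limit_eigenvalues(spec, "antisymmetric").mu_minus < 1e-6

    def test_limits_match_spectrum_near_boundary(self):
        k, eps = 2.0, 1e-8
        spec = lr.build_rank_one(30, k, -1.0 + eps, seed=4)
        summ = lr.spectrum_hd(spec)
        lim = lr.limit_eigenvalues(spec, "antisymmetric")
        assert summ.gamma_plus == pytest.approx(lim.gamma_plus, abs=1e-3)
        assert summ.mu_minus == pytest.approx(lim.mu_minus, abs=1e-3)
        assert summ.mu_plus == pytest.approx(lim.mu_plus, abs=1e-3)

    def test_unknown_regime_raises(self, rank_one_spec):
        with pytest.raises(ValueError):
            lr.limit_eigenvalues(rank_one_spec, "bogus")


class TestExport:
    def test_csv_and_json(self, tmp_path):
        import json

        import pandas as pd

        spec = lr.build_rank_one(20, 2.0, -0.5, seed=1)
        summ = lr.spectrum_hd(spec)
        summ.to_csv(tmp_path / "spectrum.csv")
        df = pd.read_csv(tmp_path / "spectrum.csv")
        assert set(df["class"]) == {"plus", "minus", "reference"}
        payload = json.loads(summ.to_json())
        assert payload["mu_ref"] == 0.5
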