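"""Robust module: ADMM updates, soft-thresholding, masked factorization."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bregnmf import (
    MaskedMatrix,
    SolverConfig,
    initialize,
    lambda_grid,
    nmf_bregman,
    robust_nmf_admm,
    soft_threshold,
    update_S,
    update_Y,
    update_dual,
)
from bregnmf.robust import RobustDecomposition

from conftest import brute_force_scalar_min


def _decomp_with(Y, S, Lam, U, V):
    from bregnmf import FactorPair

    return RobustDecomposition(
        Y=Y, S=S, factors=FactorPair(U=U, V=V, rank=U.shape[1]), Lam=Lam
    )


class TestInitialize:
    def test_fully_observed_copies_M(self, rng, default_config):
        vals = rng.random((4, 3)) + 0.1
        M = MaskedMatrix(values=vals, observed=np.ones((4, 3), bool))
        dec = initialize(M, default_config)
        np.testing.assert_array_equal(dec.Y, vals)
        assert not dec.S.any() and not dec.Lam.any()

    def test_row_mean_imputation(self, default_config):
        vals = np.array([[2.0, 4.0, 0.0]])
        obs = np.array([[True, True, False]])
        dec = initialize(MaskedMatrix(values=vals, observed=obs), default_config)
        assert dec.Y[0, 2] == pytest.approx(3.0)

    def test_empty_row_falls_back_to_global_mean(self, default_config):
        vals = np.array([[1.0, 3.0], [0.0, 0.0]])
        obs = np.array([[True, True], [False, False]])
        with pytest.warns(RuntimeWarning, match="global observed mean"):
            dec = initialize(MaskedMatrix(values=vals, observed=obs), default_config)
        np.testing.assert_allclose(dec.Y[1], [2.0, 2.0])

    def test_no_observed_entries_rejected(self, default_config):
        M = MaskedMatrix(values=np.ones((2, 2)), observed=np.zeros((2, 2), bool))
        with pytest.raises(ValueError, match="no observed"):
            initialize(M, default_config)


class TestUpdateY:
    def test_scalar_observed_case(self):
        # (UV)_ij=1, Lam=0.5, rho=1, M=3, S=0.5 -> (1+0.5+2.5)/2 = 2
        U = np.array([[1.0]])
        V = np.array([[1.0]])
        dec = _decomp_with(
            Y=np.zeros((1, 1)), S=np.array([[0.5]]), Lam=np.array([[0.5]]), U=U, V=V
        )
        M = MaskedMatrix(values=np.array([[3.0]]), observed=np.ones((1, 1), bool))
        cfg = SolverConfig(rank=1, rho_aug=1.0)
        assert update_Y(dec, M, cfg)[0, 0] == pytest.approx(2.0)

    def test_unobserved_entries_take_lowrank_value(self, rng):
        U = rng.random((3, 2)) + 0.2
        V = rng.random((4, 2)) + 0.2
        obs = np.ones((3, 4), bool)
        obs[1, 2] = False
        M = MaskedMatrix(values=rng.random((3, 4)), observed=obs)
        dec = _decomp_with(np.zeros((3, 4)), np.zeros((3, 4)), np.zeros((3, 4)), U, V)
        Y = update_Y(dec, M, SolverConfig(rank=2, rho_aug=1.0))
        assert Y[1, 2] == pytest.approx((U @ V.T)[1, 2])

    def test_large_rho_limit_tracks_M_minus_S(self, rng):
        U = rng.random((2, 1)) + 0.2
        V = rng.random((3, 1)) + 0.2
        S = rng.random((2, 3)) * 0.1
        M = MaskedMatrix(values=rng.random((2, 3)) + 1, observed=np.ones((2, 3), bool))
        dec = _decomp_with(np.zeros((2, 3)), S, np.ones((2, 3)), U, V)
        Y = update_Y(dec, M, SolverConfig(rank=1, rho_aug=1e9))
        np.testing.assert_allclose(Y, M.values - S, atol=1e-6)

    def test_matches_scalar_oracle_on_random_instances(self, rng):
        """Per-entry numeric minimization of the displayed Y-objective."""
        for rho in (0.1, 1.0, 10.0):
            U = rng.random((6, 2)) + 0.2
            V = rng.random((5, 2)) + 0.2
            UVt = U @ V.T
            S = rng.normal(size=(6, 5))
            Lam = rng.normal(size=(6, 5))
            obs = rng.random((6, 5)) > 0.2
            M = MaskedMatrix(values=rng.random((6, 5)) * 3, observed=obs)
            dec = _decomp_with(np.zeros((6, 5)), S, Lam, U, V)
            Y = update_Y(dec, M, SolverConfig(rank=2, rho_aug=rho))
            i, j = 0, 0
            obs_ij = obs[i, j]

            def f(y):
                val = 0.5 * (y - UVt[i, j]) ** 2
                if obs_ij:
                    r = M.values[i, j] - y - S[i, j]
                    val = val + Lam[i, j] * r + rho * 0.5 * r**2
                return val

            ystar = brute_force_scalar_min(f)
            assert Y[i, j] == pytest.approx(ystar, abs=1e-4)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "y,t,expected", [(5.0, 2.0, 3.0), (-5.0, 2.0, -3.0), (0.5, 1.0, 0.0),
                         (2.0, 2.0, 0.0)]
    )
    def test_known_values(self, y, t, expected):
        assert soft_threshold(y, t) == pytest.approx(expected)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.floats(-10, 10), st.floats(0, 5))
    def test_minimizes_l1_penalized_quadratic(self, y, t):
        x = soft_threshold(y, t)
        obj = lambda z: 0.5 * (y - z) ** 2 + t * abs(z)
        for dz in (-1e-4, 1e-4):
            assert obj(x) <= obj(x + dz) + 1e-12

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            soft_threshold(1.0, -0.1)


class TestUpdateS:
    def test_zero_off_omega_and_dead_zone(self, rng):
        obs = np.array([[True, False], [True, True]])
        M = MaskedMatrix(values=np.ones((2, 2)), observed=obs)
        U = np.ones((2, 1))
        V = np.ones((2, 1))
        # Y == M on observed entries: residual 0, everything in the dead zone
        dec = _decomp_with(np.ones((2, 2)), np.zeros((2, 2)), np.zeros((2, 2)), U, V)
        S = update_S(dec, M, SolverConfig(rank=1, rho_aug=1.0, lam=0.5))
        assert not S.any()

    def test_scalar_example(self):
        # M=10, Y=1, Lam=0, rho=1, lam=2 -> soft(9, 2) = 7
        U = np.ones((1, 1))
        V = np.ones((1, 1))
        dec = _decomp_with(np.array([[1.0]]), np.zeros((1, 1)), np.zeros((1, 1)), U, V)
        M = MaskedMatrix(values=np.array([[10.0]]), observed=np.ones((1, 1), bool))
        S = update_S(dec, M, SolverConfig(rank=1, rho_aug=1.0, lam=2.0))
        assert S[0, 0] == pytest.approx(7.0)

    def test_matches_scalar_oracle_on_random_instances(self, rng):
        """Per-entry numeric minimization of the displayed S-objective."""
        for rho in (0.1, 1.0, 10.0):
            for lam in (0.1, 1.0, 10.0):
                Y = rng.random((6, 5)) * 2
                Lam = rng.normal(size=(6, 5))
                M = MaskedMatrix(values=rng.random((6, 5)) * 3,
                                 observed=np.ones((6, 5), bool))
                U = np.ones((6, 1))
                V = np.ones((5, 1))
                dec = _decomp_with(Y, np.zeros((6, 5)), Lam, U, V)
                S = update_S(dec, M, SolverConfig(rank=1, rho_aug=rho, lam=lam))
                i, j = 2, 3
                r = lambda s: M.values[i, j] - Y[i, j] - s
                f = lambda s: lam * np.abs(s) + Lam[i, j] * r(s) + rho * 0.5 * r(s) ** 2
                sstar = brute_force_scalar_min(f)
                assert S[i, j] == pytest.approx(sstar, abs=1e-4)


class TestUpdateDual:
    def test_feasible_point_leaves_dual_unchanged(self, rng):
        vals = rng.random((3, 2)) + 0.1
        M = MaskedMatrix(values=vals, observed=np.ones((3, 2), bool))
        U = np.ones((3, 1))
        V = np.ones((2, 1))
        Lam = rng.normal(size=(3, 2))
        dec = _decomp_with(vals.copy(), np.zeros((3, 2)), Lam, U, V)
        np.testing.assert_allclose(update_dual(dec, M), Lam)

    def test_residual_accumulates_on_omega_only(self):
        obs = np.array([[True, False]])
        M = MaskedMatrix(values=np.array([[1.0, 0.0]]), observed=obs)
        U = np.ones((1, 1))
        V = np.ones((2, 1))
        dec = _decomp_with(np.array([[0.7, 5.0]]), np.zeros((1, 2)),
                           np.zeros((1, 2)), U, V)
        Lam = update_dual(dec, M)
        assert Lam[0, 0] == pytest.approx(0.3)
        assert Lam[0, 1] == 0.0


class TestRobustADMM:
    def test_invariants_and_history(self, small_masked):
        cfg = SolverConfig(rank=2, seed=3, admm_max_iter=200)
        dec = robust_nmf_admm(small_masked, cfg)
        off = ~small_masked.observed
        assert not dec.S[off].any()
        assert not dec.Lam[off].any()
        assert (dec.factors.U > 0).all() and (dec.factors.V > 0).all()
        h = dec.history
        assert len(h["primal_residual"]) == dec.n_iter
        assert h["primal_residual"][-1] <= h["primal_residual"][0]

    def test_same_seed_bit_identical(self, small_masked):
        cfg = SolverConfig(rank=2, seed=3, admm_max_iter=100)
        a = robust_nmf_admm(small_masked, cfg)
        b = robust_nmf_admm(small_masked, cfg)
        np.testing.assert_array_equal(a.Y, b.Y)
        np.testing.assert_array_equal(a.S, b.S)
        np.testing.assert_array_equal(a.Lam, b.Lam)

    def test_lambda_at_grid_max_matches_plain_nmf(self):
        from bregnmf import make_toy

        inst = make_toy(d=20, n=15, r=3, seed=7)
        M = inst.M_observed
        cfg = SolverConfig(rank=3, seed=8)
        lam_max = float(lambda_grid(M, cfg, 5)[-1])
        dec = robust_nmf_admm(M, dataclasses.replace(cfg, lam=lam_max))
        assert not dec.S.any()
        plain = nmf_bregman(
            M.values, dataclasses.replace(cfg, outer_max_iter=2000, outer_tol=1e-12)
        )
        fa = dec.factors.product()
        fp = plain.factors.product()
        assert np.linalg.norm(fa - fp) / np.linalg.norm(fp) < 0.05

    def test_imputation_recovery_small(self):
        """Rank-3 completion: missing entries recovered within 10% of data RMS."""
        from bregnmf import inject_missing, inject_outliers, make_toy

        inst = make_toy(d=40, n=30, r=3, seed=51)
        inst = inject_outliers(inst, 0.0, seed=52)
        inst = inject_missing(inst, 0.10, seed=53)
        M = inst.M_observed
        cfg = SolverConfig(rank=3, seed=54)
        lam_max = float(lambda_grid(M, cfg, 5)[-1])
        dec = robust_nmf_admm(M, dataclasses.replace(cfg, lam=lam_max))
        miss = ~M.observed
        rmse = np.sqrt(np.mean((dec.Y[miss] - inst.M_clean[miss]) ** 2))
        rms = np.sqrt(np.mean(M.values[M.observed] ** 2))
        assert rmse < 0.10 * rms

    def test_S_l1_monotone_in_lambda(self):
        from bregnmf import inject_outliers, make_toy

        inst = make_toy(d=20, n=15, r=2, seed=41)
        inst = inject_outliers(inst, 0.05, 10.0, seed=42)
        M = inst.M_observed
        cfg = SolverConfig(rank=2, seed=43)
        grid = lambda_grid(M, cfg, 8)
        l1 = [
            np.abs(robust_nmf_admm(M, dataclasses.replace(cfg, lam=float(g))).S).sum()
            for g in grid
        ]
        for a, b in zip(l1, l1[1:]):
            assert b <= a * 1.01

    def test_rank_too_large_rejected(self, small_masked):
        with pytest.raises(ValueError, match="rank"):
            robust_nmf_admm(small_masked, SolverConfig(rank=6))
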