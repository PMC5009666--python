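"""Outlier-robust, missing-data NMF via an augmented-Lagrangian ADMM.

The masked problem splits the data M on its observation set Omega as
M = Y + S, where Y is a denoised/completed matrix fitted by a non-negative
low-rank product U V^t and S is a sparse outlier matrix penalized in l1:

    min_{Y,S,U,V >= 0}  1/2 sum_{(i,j) in Omega} (Y_ij - (U V^t)_ij)^2
                        + lam ||S||_1     s.t.  M = Y + S on Omega.

Each ADMM sweep minimizes the augmented Lagrangian in Y (closed form),
S (entrywise soft-thresholding), then U and V (Bregman fixed-point solves
against the current Y), and finishes with a dual ascent on the multipliers.
S and the multipliers live on Omega only; off Omega the completion is driven
purely by the low-rank fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    FactorPair,
    MaskedMatrix,
    SolverConfig,
    SolverError,
    fixed_point_update_U,
    fixed_point_update_V,
    init_factors,
)

logger = logging.getLogger("bregnmf")


@dataclass
class RobustDecomposition:
    """Full ADMM state: completed data, outliers, factors, multipliers.

    ``Y`` is the denoised/completed matrix exposed to users (also on missing
    entries); ``S`` holds the sparse outliers and ``Lam`` the dual
    multipliers, both supported on the observation set only.  ``history``
    carries per-iteration diagnostics: ``primal_residual`` (max |M - Y - S|
    over Omega), ``dual_distance`` (Frobenius distance between successive
    multiplier iterates) and ``rel_error`` (relative Frobenius error between
    M and U V^t on Omega).
    """

    Y: np.ndarray
    S: np.ndarray
    factors: FactorPair
    Lam: np.ndarray
    history: dict[str, list[float]] = field(default_factory=dict)
    converged: bool = False
    n_iter: int = 0

    def lowrank(self) -> np.ndarray:
        """The factor reconstruction U V^t (reported alongside Y)."""
        return self.factors.product()


def initialize(M: MaskedMatrix, config: SolverConfig) -> RobustDecomposition:
    """Starting point of the ADMM.

    Factors are random positive (seeded); S and the multipliers start at
    zero; Y starts at M on observed entries and at the row mean of the
    observed entries elsewhere.  A row with no observed entry falls back to
    the global mean of all observed entries (with a warning).
    """
    if M.n_observed == 0:
        raise ValueError("M has no observed entries")
    d, n = M.shape
    obs = M.observed
    vals = M.filled(0.0)

    row_counts = obs.sum(axis=1)
    global_mean = vals[obs].mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        row_means = np.where(
            row_counts > 0, vals.sum(axis=1) / np.maximum(row_counts, 1), global_mean
        )
    if (row_counts == 0).any():
        empty = np.flatnonzero(row_counts == 0)
        warnings.warn(
            f"rows {empty.tolist()} have no observed entries; imputing with "
            f"the global observed mean {global_mean:.6g}",
            RuntimeWarning,
            stacklevel=2,
        )
    Y0 = np.where(obs, vals, row_means[:, None])

    return RobustDecomposition(
        Y=Y0,
        S=np.zeros((d, n)),
        factors=init_factors(d, n, config),
        Lam=np.zeros((d, n)),
    )


def update_Y(
    decomp: RobustDecomposition, M: MaskedMatrix, config: SolverConfig
) -> np.ndarray:
    """Closed-form minimizer of the augmented Lagrangian in Y.

    On observed entries Y = ((U V^t) + Lam + rho (M - S)) / (1 + rho) with
    rho = ``config.rho_aug``; off the observation set the quadratic fit term
    alone is active and Y = (U V^t).
    """
    UVt = decomp.factors.product()
    rho = config.rho_aug
    obs = M.observed
    vals = M.filled(0.0)
    Y_obs = (UVt + decomp.Lam + rho * (vals - decomp.S)) / (1.0 + rho)
    return np.where(obs, Y_obs, UVt)


def soft_threshold(y, t):
    """Proximal operator of t|.|: the minimizer of 1/2 (y - x)^2 + t |x|.

    Returns y - t where y > t, y + t where y < -t, and 0 on the closed dead
    zone |y| <= t.  Accepts scalars or arrays; t must be non-negative.
    """
    t = np.asarray(t, dtype=float)
    if (t < 0).any():
        raise ValueError("threshold must be non-negative")
    y = np.asarray(y, dtype=float)
    out = np.sign(y) * np.maximum(np.abs(y) - t, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def update_S(
    decomp: RobustDecomposition, M: MaskedMatrix, config: SolverConfig
) -> np.ndarray:
    """Entrywise minimizer of the augmented Lagrangian in S.

    On observed entries S = soft_threshold(M - Y + Lam/rho, lam/rho); off
    the observation set S = 0 (the l1 term alone is active there).
    """
    if config.lam < 0:
        raise ValueError("lam must be non-negative")
    rho = config.rho_aug
    resid = M.filled(0.0) - decomp.Y + decomp.Lam / rho
    S = soft_threshold(resid, config.lam / rho)
    return np.where(M.observed, S, 0.0)


def update_dual(
    decomp: RobustDecomposition, M: MaskedMatrix, config: SolverConfig | None = None
) -> np.ndarray:
    """Dual ascent on the multipliers, restricted to the observation set.

    Lam <- Lam + step * (M - Y - S) on Omega; unit step by default, or
    rho_aug (the standard augmented-Lagrangian pairing) when
    ``config.dual_step_scaled`` is set.
    """
    step = 1.0
    if config is not None and config.dual_step_scaled:
        step = config.rho_aug
    resid = M.filled(0.0) - decomp.Y - decomp.S
    return np.where(M.observed, decomp.Lam + step * resid, 0.0)


def _check_finite(name: str, A: np.ndarray, k: int) -> None:
    if not np.isfinite(A).all():
        raise SolverError(f"non-finite value in {name} at outer iteration {k}")


def robust_nmf_admm(M: MaskedMatrix, config: SolverConfig) -> RobustDecomposition:
    """Run the full ADMM on a masked matrix.

    Per outer iteration, in order: Y-update, S-update, U fixed-point solve,
    V fixed-point solve, dual ascent.  The factor solves fit the current Y,
    which carries the data through the coupling terms (M itself has holes
    and outliers).  Terminates at ``admm_max_iter`` or when both the primal
    residual on the observed set and the successive-multiplier distance
    fall below ``admm_tol``.
    """
    d, n = M.shape
    if config.rank > min(d, n):
        raise ValueError(f"rank {config.rank} exceeds min(d, n) = {min(d, n)}")
    decomp = initialize(M, config)
    history: dict[str, list[float]] = {
        "primal_residual": [],
        "dual_distance": [],
        "rel_error": [],
    }
    obs = M.observed
    vals = M.filled(0.0)
    norm_obs = np.linalg.norm(vals[obs])

    for k in range(1, config.admm_max_iter + 1):
        decomp.Y = update_Y(decomp, M, config)
        _check_finite("Y", decomp.Y, k)
        decomp.S = update_S(decomp, M, config)
        _check_finite("S", decomp.S, k)

        U = fixed_point_update_U(
            decomp.Y,
            decomp.factors.U,
            decomp.factors.V,
            config.rho_prox,
            config.inner_tol,
            config.inner_max_iter,
            config.inner_damping,
        ).matrix
        V = fixed_point_update_V(
            decomp.Y,
            decomp.factors.V,
            U,
            config.rho_prox,
            config.inner_tol,
            config.inner_max_iter,
            config.inner_damping,
        ).matrix
        decomp.factors = FactorPair(U=U, V=V, rank=config.rank)

        Lam_new = update_dual(decomp, M, config)
        _check_finite("Lam", Lam_new, k)

        primal = float(np.abs((vals - decomp.Y - decomp.S))[obs].max())
        dual_dist = float(np.linalg.norm(Lam_new - decomp.Lam))
        fit = decomp.factors.product()
        rel_err = float(
            np.linalg.norm((vals - fit)[obs]) / max(norm_obs, 1e-300)
        )
        history["primal_residual"].append(primal)
        history["dual_distance"].append(dual_dist)
        history["rel_error"].append(rel_err)
        decomp.Lam = Lam_new
        decomp.n_iter = k

        if primal < config.admm_tol and dual_dist < config.admm_tol:
            decomp.converged = True
            break

    decomp.history = history
    logger.debug(
        "robust_nmf_admm: %d iterations, primal %.3e, rel_error %.3e",
        decomp.n_iter,
        history["primal_residual"][-1],
        history["rel_error"][-1],
    )
    return decomp
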