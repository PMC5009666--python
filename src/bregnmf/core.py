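"""Entropic Bregman divergence and the Bregman-proximal alternating NMF scheme.

This module handles the fully observed, outlier-free case: a non-negative
matrix M is approximated by a product U V^t of strictly positive factors by
alternating proximal steps, where the proximal term is the Bregman divergence
generated by the negative entropy h(x) = x ln x.  The entropic divergence is
finite only on the positive orthant, so the scheme keeps every iterate
automatically positive without projections.

Each proximal subproblem

    argmin_U  1/2 ||M - U V^t||_F^2 + rho * D_h(U, U_prev)

has no closed form; its stationarity condition

    (M - U V^t) V = rho * ln(U / U_prev)    (entrywise)

is solved by the fixed-point iteration

    U <- exp( (1/rho) [(M - U V^t) V] + ln U_prev ),

stopped when successive iterates differ by less than ``inner_tol`` in the
entrywise max norm.

The raw fixed-point map has a negative Jacobian whose spectral radius
approaches 1 when ||V^t V|| is comparable to rho, which makes the plain
iteration oscillate with period 2 and eventually diverge at moderate
problem sizes.  The implementation therefore applies geometric damping in
the log domain,

    ln U_new = (1 - alpha) ln U + alpha [ G(U)/rho + ln U_prev ],

which has exactly the same fixed points (the stationarity equation is
unchanged) but halves the Jacobian's distance to the unit circle at the
default alpha = 1/2; alpha = 1 recovers the undamped map.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

logger = logging.getLogger("bregnmf")

# exponent clamp for the exponential update: exp(+-50) stays finite in float64
# while still being far outside any sensible factor scale
_EXP_CLAMP = 50.0
# largest log-domain change per inner sweep and smallest adaptive damping
_MAX_LOG_STEP = 1.0
_MIN_DAMPING = 0.05


class SolverError(RuntimeError):
    """Raised when a solver produces non-finite iterates."""


def _require_positive(A: np.ndarray, name: str) -> None:
    """Raise if any entry of ``A`` is non-positive, naming the first offender."""
    bad = ~(A > 0)
    if bad.any():
        idx = tuple(int(k) for k in np.argwhere(bad)[0])
        raise ValueError(
            f"{name} must be strictly positive; entry {idx} is {A[idx]!r}"
        )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MaskedMatrix:
    """A data matrix together with its observation set Omega.

    Parameters
    ----------
    values
        d x n array.  Entries at unobserved positions are ignored (NaN is
        allowed there).
    observed
        d x n boolean mask; True marks an observed entry.

    Observed entries must be finite and non-negative (NMF domain).
    """

    values: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d array")
        if self.values.shape != self.observed.shape:
            raise ValueError(
                f"mask shape {self.observed.shape} does not match "
                f"values shape {self.values.shape}"
            )
        obs = self.values[self.observed]
        if not np.all(np.isfinite(obs)):
            raise ValueError("observed entries must be finite")
        if obs.size and obs.min() < 0:
            idx = tuple(
                int(k)
                for k in np.argwhere(self.observed & (self.values < 0))[0]
            )
            raise ValueError(
                f"observed entry {idx} is negative ({self.values[idx]}); "
                "the factorization domain is non-negative"
            )

    @classmethod
    def from_dense(cls, values: np.ndarray) -> "MaskedMatrix":
        """Build a MaskedMatrix from a dense array, treating NaN as missing."""
        values = np.asarray(values, dtype=float)
        return cls(values=values, observed=~np.isnan(values))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_observed(self) -> int:
        return int(self.observed.sum())

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Dense copy with unobserved entries replaced by ``fill``."""
        return np.where(self.observed, self.values, fill)


@dataclass
class FactorPair:
    """Strictly positive factors U (d x r) and V (n x r) with target rank r."""

    U: np.ndarray
    V: np.ndarray
    rank: int

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.U.shape[1] != self.rank or self.V.shape[1] != self.rank:
            raise ValueError(
                f"factor column counts {self.U.shape[1]}, {self.V.shape[1]} "
                f"must both equal rank {self.rank}"
            )
        _require_positive(self.U, "U")
        _require_positive(self.V, "V")

    def product(self) -> np.ndarray:
        """The low-rank reconstruction U V^t."""
        return self.U @ self.V.T


@dataclass
class SolverConfig:
    """Tuning parameters shared by the plain and robust solvers.

    Attributes
    ----------
    rho_prox
        Weight of the entropic Bregman proximal term in the factor updates.
        Larger values take smaller, safer steps.
    rho_aug
        Augmented-Lagrangian penalty enforcing M = Y + S on the observed set.
    lam
        Sparsity weight on the outlier matrix S (the l1 penalty).
    rank
        Number of factors r.
    inner_tol, inner_max_iter
        Stopping rule for the fixed-point inner loop: stop when the max
        absolute entrywise change between successive iterates drops below
        ``inner_tol``.
    inner_damping
        Log-domain damping of the inner fixed-point map (1 = undamped).
    outer_max_iter, outer_tol
        Outer loop of the plain alternating scheme: cap, and relative-change
        tolerance on the Frobenius error trace.
    admm_max_iter, admm_tol
        Outer loop of the robust ADMM: cap, and tolerance applied to both the
        primal residual (max over observed entries) and the Frobenius distance
        between successive dual iterates.
    positivity_floor
        Lower endpoint of the Uniform initialization of the factors; keeps
        logarithms finite.
    dual_step_scaled
        If True the dual ascent uses step length rho_aug (standard ADMM
        scaling) instead of the unit step.
    seed
        Seed for the factor initialization.
    """

    rank: int = 2
    rho_prox: float = 100.0
    rho_aug: float = 1.0
    lam: float = 1.0
    inner_tol: float = 1e-3
    inner_max_iter: int = 50
    inner_damping: float = 0.5
    outer_max_iter: int = 100
    outer_tol: float = 1e-6
    admm_max_iter: int = 2000
    admm_tol: float = 1e-5
    positivity_floor: float = 1e-6
    dual_step_scaled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be a positive integer")
        if self.rho_prox <= 0 or self.rho_aug <= 0:
            raise ValueError("rho_prox and rho_aug must be positive")
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if self.inner_tol <= 0 or self.outer_tol <= 0 or self.admm_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not (0 < self.positivity_floor < 1):
            raise ValueError("positivity_floor must lie in (0, 1)")
        if not (0 < self.inner_damping <= 1):
            raise ValueError("inner_damping must lie in (0, 1]")


class FixedPointResult(NamedTuple):
    """Output of one inner fixed-point solve."""

    matrix: np.ndarray
    n_iter: int
    converged: bool


@dataclass
class NMFResult:
    """Factors and the per-outer-iteration Frobenius error trace."""

    factors: FactorPair
    trace: np.ndarray
    converged: bool
    n_iter: int = field(default=0)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def bregman_divergence(Y: np.ndarray, X: np.ndarray) -> float:
    """Entropic Bregman divergence sum_ij Y ln(Y/X) - Y + X.

    This is the divergence generated by h(x) = x ln x: the generalized
    Kullback-Leibler divergence, non-negative and zero iff X == Y.  Both
    arguments must be strictly positive and of identical shape.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.shape != X.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {X.shape}")
    _require_positive(Y, "Y")
    _require_positive(X, "X")
    return float(np.sum(Y * np.log(Y / X) - Y + X))


def fixed_point_update_U(
    M: np.ndarray,
    U_prev: np.ndarray,
    V: np.ndarray,
    rho_prox: float,
    inner_tol: float = 1e-3,
    inner_max_iter: int = 50,
    damping: float = 0.5,
) -> FixedPointResult:
    """Solve the Bregman-proximal U-subproblem by damped fixed-point iteration.

    Iterates the log-domain map ``ln U <- (1-damping) ln U +
    damping (grad/rho + ln U_prev)`` with ``grad = (M - U V^t) V``,
    starting from ``U_prev``, until the max absolute entrywise change
    falls below ``inner_tol`` or the iteration cap is reached.  The
    damped map shares its fixed points with the undamped one
    (``damping=1``) but stays contractive where the plain iteration
    oscillates.  The exponent is clamped to +-50 (with a warning) to
    avoid overflow for small ``rho_prox``; the output is always strictly
    positive.
    """
    M = np.asarray(M, dtype=float)
    U_prev = np.asarray(U_prev, dtype=float)
    V = np.asarray(V, dtype=float)
    if not 0 < damping <= 1:
        raise ValueError("damping must lie in (0, 1]")
    _require_positive(U_prev, "U_prev")
    log_prev = np.log(U_prev)

    U = U_prev
    log_U = log_prev
    alpha = damping
    prev_delta = np.inf
    n_iter = 0
    converged = False
    for l in range(1, inner_max_iter + 1):
        target = ((M - U @ V.T) @ V) / rho_prox + log_prev
        if np.isnan(target).any():
            raise SolverError(f"NaN in fixed-point update at inner iteration {l}")
        step = alpha * (target - log_U)
        # trust cap: at most one e-fold of multiplicative change per sweep,
        # so a transiently huge gradient cannot launch the iterate
        max_step = np.abs(step).max()
        if max_step > _MAX_LOG_STEP:
            step *= _MAX_LOG_STEP / max_step
        exponent = log_U + step
        if np.abs(exponent).max() > _EXP_CLAMP:
            warnings.warn(
                "fixed-point exponent clamped to +-50; consider a larger "
                "rho_prox",
                RuntimeWarning,
                stacklevel=2,
            )
            exponent = np.clip(exponent, -_EXP_CLAMP, _EXP_CLAMP)
        U_new = np.exp(exponent)
        delta = np.abs(U_new - U).max()
        if delta > prev_delta:
            # oscillation guard: the map is locally expansive, shrink the step
            alpha = max(alpha / 2.0, _MIN_DAMPING)
        prev_delta = delta
        U = U_new
        log_U = exponent
        n_iter = l
        if delta < inner_tol:
            converged = True
            break
    return FixedPointResult(U, n_iter, converged)


def fixed_point_update_V(
    M: np.ndarray,
    V_prev: np.ndarray,
    U: np.ndarray,
    rho_prox: float,
    inner_tol: float = 1e-3,
    inner_max_iter: int = 50,
    damping: float = 0.5,
) -> FixedPointResult:
    """V-subproblem: identical to the U-update applied to M^t with U, V swapped."""
    return fixed_point_update_U(
        np.asarray(M, dtype=float).T, V_prev, U, rho_prox, inner_tol,
        inner_max_iter, damping
    )


def init_factors(d: int, n: int, config: SolverConfig) -> FactorPair:
    """Random strictly positive factors, i.i.d. Uniform(positivity_floor, 1]."""
    rng = np.random.default_rng(config.seed)
    lo = config.positivity_floor
    U = lo + (1.0 - lo) * rng.random((d, config.rank))
    V = lo + (1.0 - lo) * rng.random((n, config.rank))
    return FactorPair(U=U, V=V, rank=config.rank)


def nmf_bregman(M: np.ndarray, config: SolverConfig) -> NMFResult:
    """Alternating Bregman-proximal NMF of a fully observed matrix.

    Alternates the U and V fixed-point solves, recording the Frobenius
    error ||M - U V^t||_F after every outer iteration.  Stops at
    ``outer_max_iter`` or when the relative change of the error trace
    drops below ``outer_tol``.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("M must be a 2-d array")
    d, n = M.shape
    if config.rank > min(d, n):
        raise ValueError(
            f"rank {config.rank} exceeds min(d, n) = {min(d, n)}"
        )
    if not np.isfinite(M).all() or M.min() < 0:
        raise ValueError("M must be fully observed, finite and non-negative")

    if not M.any():
        warnings.warn(
            "all-zero input matrix: returning factors at the positivity floor",
            RuntimeWarning,
            stacklevel=2,
        )
        floor = config.positivity_floor
        factors = FactorPair(
            U=np.full((d, config.rank), floor),
            V=np.full((n, config.rank), floor),
            rank=config.rank,
        )
        err = float(np.linalg.norm(M - factors.product()))
        return NMFResult(factors, np.asarray([err]), converged=True, n_iter=1)

    factors = init_factors(d, n, config)
    U, V = factors.U, factors.V
    trace: list[float] = []
    converged = False
    for k in range(1, config.outer_max_iter + 1):
        U = fixed_point_update_U(
            M, U, V, config.rho_prox, config.inner_tol, config.inner_max_iter,
            config.inner_damping,
        ).matrix
        V = fixed_point_update_V(
            M, V, U, config.rho_prox, config.inner_tol, config.inner_max_iter,
            config.inner_damping,
        ).matrix
        err = float(np.linalg.norm(M - U @ V.T))
        trace.append(err)
        if k > 1:
            prev = trace[-2]
            if abs(prev - err) < config.outer_tol * max(prev, 1e-300):
                converged = True
                break
    logger.debug("nmf_bregman: %d outer iterations, final error %.3e", len(trace), trace[-1])
    return NMFResult(
        FactorPair(U=U, V=V, rank=config.rank),
        np.asarray(trace),
        converged=converged,
        n_iter=len(trace),
    )
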