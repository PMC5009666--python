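"""Holdout selection of the outlier-sparsity parameter lambda.

The sparsity weight lambda trades off how much of the data is explained by
the sparse outlier matrix S versus the low-rank fit.  It is chosen by
entrywise cross-validation: a set of observed entries is artificially
declared missing, the robust solver is run for each lambda on a log-spaced
grid, and the lambda minimizing the mean squared prediction error on the
held-out entries is selected.

The top of the grid is constructed so that the very first S-update
thresholds every residual to zero (the dead-zone condition), which
guarantees that at the grid maximum the solver starts in the pure
low-rank-completion regime with S = 0.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import MaskedMatrix, SolverConfig
from . import robust

logger = logging.getLogger("bregnmf")


@dataclass
class CVReport:
    """Grid, holdout set, per-lambda errors and the selected lambda."""

    grid: np.ndarray
    holdout: list[tuple[int, int]]
    errs: np.ndarray
    selected: float
    seed: int


def lambda_grid(
    M: MaskedMatrix, config: SolverConfig, n_points: int = 20
) -> np.ndarray:
    """Log-spaced grid from lambda_max/1000 to lambda_max.

    lambda_max is the largest initial fit residual over the observed set,
    max |M - (U0 V0^t)| with the seeded starting factors.  This bound
    plays two roles.  First, the residual entering the first S-update is
    (M - U0 V0^t)/(1 + rho), so the dead-zone condition of
    soft-thresholding (|residual| <= lam/rho) zeroes the entire first
    S-update for every lam >= lambda_max, whatever rho_aug.  Second, the
    stationarity condition for S = 0 at the solution is that every
    multiplier |Lam*| = |M - (U V^t)*| stays below lam, and the converged
    fit residuals do not exceed the initial ones, so the top of the grid
    keeps S identically zero through the whole run.
    """
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    decomp = robust.initialize(M, config)
    resid = np.abs(M.filled(0.0) - decomp.factors.product())
    lam_max = float(resid[M.observed].max())
    if lam_max == 0.0:
        warnings.warn(
            "all initial residuals are zero; returning the degenerate grid {1}",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.asarray([1.0])
    return np.geomspace(lam_max / 1000.0, lam_max, n_points)


def holdout_split(
    M: MaskedMatrix, s: int, seed: int
) -> tuple[MaskedMatrix, list[tuple[int, int]]]:
    """Declare s observed entries missing, uniformly at random.

    Returns the reduced MaskedMatrix and the list of held-out positions
    (their true values stay available in ``M``).  Reproducible from seed.
    """
    n_obs = M.n_observed
    if not 1 <= s < n_obs:
        raise ValueError(f"s must satisfy 1 <= s < {n_obs}, got {s}")
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(M.observed)
    pick = rng.choice(len(obs_idx), size=s, replace=False)
    holdout = [tuple(int(k) for k in obs_idx[p]) for p in pick]
    mask = M.observed.copy()
    for i, j in holdout:
        mask[i, j] = False
    return MaskedMatrix(values=M.values, observed=mask), holdout


def score_lambda(
    M: MaskedMatrix,
    holdout: list[tuple[int, int]],
    lam: float,
    config: SolverConfig,
) -> float:
    """Mean squared error of the completed Y on the held-out entries."""
    if not holdout:
        raise ValueError("holdout must be non-empty")
    mask = M.observed.copy()
    for i, j in holdout:
        mask[i, j] = False
    reduced = MaskedMatrix(values=M.values, observed=mask)
    cfg = dataclasses.replace(config, lam=float(lam))
    try:
        decomp = robust.robust_nmf_admm(reduced, cfg)
    except Exception as exc:
        raise RuntimeError(f"solver failed at lambda={lam:.6g}") from exc
    sq = [(M.values[i, j] - decomp.Y[i, j]) ** 2 for i, j in holdout]
    return float(np.mean(sq))


def select_lambda(
    M: MaskedMatrix,
    config: SolverConfig,
    n_points: int = 20,
    s: int | None = None,
    seed: int = 0,
    repeats: int = 1,
) -> CVReport:
    """Build the grid, hold out entries, score every lambda, pick the argmin.

    One holdout split is shared across the whole grid so the per-lambda
    errors are comparable; with ``repeats`` > 1 the errors are averaged over
    that many independent splits.  The default holdout size is 5 % of the
    observed entries.  Ties select the smallest lambda.
    """
    grid = lambda_grid(M, config, n_points)
    if s is None:
        s = max(1, math.ceil(0.05 * M.n_observed))
    errs = np.zeros(len(grid))
    first_holdout: list[tuple[int, int]] = []
    for r in range(repeats):
        split_seed = seed + r
        _, holdout = holdout_split(M, s, split_seed)
        if r == 0:
            first_holdout = holdout
        for g, lam in enumerate(grid):
            errs[g] += score_lambda(M, holdout, lam, config)
            logger.debug("lambda=%.4g err=%.6g (split %d)", lam, errs[g], r)
    errs /= repeats
    selected = float(grid[int(np.argmin(errs))])
    logger.info("selected lambda = %.6g", selected)
    return CVReport(
        grid=np.asarray(grid),
        holdout=first_holdout,
        errs=errs,
        selected=selected,
        seed=seed,
    )
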