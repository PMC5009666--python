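"""Synthetic data: low-rank ground truth plus outliers, missingness and noise.

The generator emulates the statistical structure the robust factorization
assumes in gene-expression data: an exactly low-rank non-negative signal
(U0 V0^t with uniform factors), sparse large-magnitude corruptions, a
uniformly random missingness mask, and dense centered noise.  Corruptions
are applied in one canonical order — outliers, then missingness, then
noise — and every instance records the parameters needed to regenerate it
bit-exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import MaskedMatrix

_STAGES = ("outliers", "missing", "noise")


@dataclass
class SyntheticInstance:
    """A generated instance with full ground truth retained for scoring."""

    M_clean: np.ndarray
    U0: np.ndarray
    V0: np.ndarray
    M_observed: MaskedMatrix
    S_true: np.ndarray
    noise_sigma: float
    seed: int
    metadata: dict = field(default_factory=dict)
    n_clipped: int = 0

    @property
    def outlier_positions(self) -> np.ndarray:
        """Boolean mask of the injected outlier support."""
        return self.S_true != 0


def _require_order(inst: SyntheticInstance, stage: str) -> None:
    if stage in inst.metadata:
        raise ValueError(f"{stage} already applied to this instance")
    idx = _STAGES.index(stage)
    later = [s for s in _STAGES[idx + 1:] if s in inst.metadata]
    if later:
        raise ValueError(
            f"corruption order is {' -> '.join(_STAGES)}; "
            f"cannot apply {stage} after {later[0]}"
        )


def _data_rms(inst: SyntheticInstance) -> float:
    vals = inst.M_observed.values[inst.M_observed.observed]
    return float(np.sqrt(np.mean(vals**2)))


def make_toy(d: int = 50, n: int = 70, r: int = 8, seed: int = 0) -> SyntheticInstance:
    """Exactly low-rank instance: U0 (d x r) and V0 (n x r) i.i.d. Uniform[0,1].

    M = U0 V0^t, fully observed, no noise, no outliers.  The defaults match
    a 50 x 70 rank-8 configuration.
    """
    if not (min(d, n) >= r >= 1):
        raise ValueError(f"need d, n >= r >= 1, got d={d}, n={n}, r={r}")
    rng = np.random.default_rng(seed)
    U0 = rng.random((d, r))
    V0 = rng.random((n, r))
    M = U0 @ V0.T
    return SyntheticInstance(
        M_clean=M,
        U0=U0,
        V0=V0,
        M_observed=MaskedMatrix(values=M.copy(), observed=np.ones((d, n), bool)),
        S_true=np.zeros((d, n)),
        noise_sigma=0.0,
        seed=seed,
        metadata={"d": d, "n": n, "r": r, "seed": seed},
    )


def inject_outliers(
    inst: SyntheticInstance, fraction: float, magnitude: float = 10.0, seed: int = 0
) -> SyntheticInstance:
    """Add sparse spikes of size magnitude * data RMS with random signs.

    ceil(fraction * d * n) positions are sampled without replacement; the
    spike values are recorded in S_true and added to the observed matrix.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    _require_order(inst, "outliers")
    d, n = inst.M_clean.shape
    k = math.ceil(fraction * d * n)
    S = np.zeros((d, n))
    vals = inst.M_observed.values.copy()
    if k > 0:
        rng = np.random.default_rng(seed)
        flat = rng.choice(d * n, size=k, replace=False)
        signs = rng.choice([-1.0, 1.0], size=k)
        scale = magnitude * _data_rms(inst)
        rows, cols = np.unravel_index(flat, (d, n))
        S[rows, cols] = signs * scale
        vals = np.maximum(vals + S, 0.0)  # keep the observed matrix in the NMF domain
        S[rows, cols] = vals[rows, cols] - inst.M_observed.values[rows, cols]
    meta = dict(inst.metadata)
    meta["outliers"] = {"fraction": fraction, "magnitude": magnitude, "seed": seed}
    return SyntheticInstance(
        M_clean=inst.M_clean,
        U0=inst.U0,
        V0=inst.V0,
        M_observed=MaskedMatrix(values=vals, observed=inst.M_observed.observed.copy()),
        S_true=S,
        noise_sigma=inst.noise_sigma,
        seed=inst.seed,
        metadata=meta,
    )


def inject_missing(
    inst: SyntheticInstance,
    fraction: float,
    seed: int = 0,
    protected: set[tuple[int, int]] | None = None,
) -> SyntheticInstance:
    """Mark ceil(fraction * d * n) entries unobserved, uniformly at random.

    Ground truth stays available for scoring.  Positions in ``protected``
    are never masked.  If the sampled mask would empty a row the draw is
    repeated once; if the second draw also empties a row a warning is
    emitted and the mask is kept (exercising the initializer's global-mean
    fallback).
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    _require_order(inst, "missing")
    d, n = inst.M_clean.shape
    k = math.ceil(fraction * d * n)
    observed = inst.M_observed.observed.copy()
    if k > 0:
        candidates = np.flatnonzero(observed.ravel())
        if protected:
            prot = {i * n + j for i, j in protected}
            candidates = np.asarray([c for c in candidates if c not in prot])
        k = min(k, len(candidates))
        for attempt in range(2):
            rng = np.random.default_rng(seed + attempt)
            flat = rng.choice(candidates, size=k, replace=False)
            mask = observed.copy()
            mask.ravel()[flat] = False
            if mask.any(axis=1).all():
                break
        else:
            warnings.warn(
                "missingness mask empties at least one row after resampling",
                RuntimeWarning,
                stacklevel=2,
            )
        observed = mask
    meta = dict(inst.metadata)
    meta["missing"] = {
        "fraction": fraction,
        "seed": seed,
        "protected": sorted(protected) if protected else None,
    }
    return SyntheticInstance(
        M_clean=inst.M_clean,
        U0=inst.U0,
        V0=inst.V0,
        M_observed=MaskedMatrix(values=inst.M_observed.values.copy(), observed=observed),
        S_true=inst.S_true.copy(),
        noise_sigma=inst.noise_sigma,
        seed=inst.seed,
        metadata=meta,
    )


def add_noise(inst: SyntheticInstance, sigma: float, seed: int = 0) -> SyntheticInstance:
    """Add centered Gaussian noise of SD sigma * data RMS to observed entries.

    Negative results are clipped at zero to preserve non-negativity; the
    number of clipped entries is reported on the instance.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    _require_order(inst, "noise")
    vals = inst.M_observed.values.copy()
    n_clipped = 0
    if sigma > 0:
        rng = np.random.default_rng(seed)
        obs = inst.M_observed.observed
        noise = rng.normal(0.0, sigma * _data_rms(inst), size=vals.shape)
        noisy = vals + np.where(obs, noise, 0.0)
        n_clipped = int(((noisy < 0) & obs).sum())
        vals = np.maximum(noisy, 0.0)
    meta = dict(inst.metadata)
    meta["noise"] = {"sigma": sigma, "seed": seed}
    return SyntheticInstance(
        M_clean=inst.M_clean,
        U0=inst.U0,
        V0=inst.V0,
        M_observed=MaskedMatrix(values=vals, observed=inst.M_observed.observed.copy()),
        S_true=inst.S_true.copy(),
        noise_sigma=sigma,
        seed=inst.seed,
        metadata=meta,
        n_clipped=n_clipped,
    )


def from_metadata(meta: dict) -> SyntheticInstance:
    """Regenerate an instance bit-exactly from its recorded parameters."""
    inst = make_toy(d=meta["d"], n=meta["n"], r=meta["r"], seed=meta["seed"])
    if "outliers" in meta:
        o = meta["outliers"]
        inst = inject_outliers(inst, o["fraction"], o["magnitude"], o["seed"])
    if "missing" in meta:
        m = meta["missing"]
        prot = {tuple(p) for p in m["protected"]} if m.get("protected") else None
        inst = inject_missing(inst, m["fraction"], m["seed"], protected=prot)
    if "noise" in meta:
        nz = meta["noise"]
        inst = add_noise(inst, nz["sigma"], nz["seed"])
    return inst
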