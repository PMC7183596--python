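"""Weight learning for the six-feature linear score.

Two fitters are provided:

* ordinary least squares of GDT-TS on the pooled features, with the intercept
  fitted and then discarded — only the ranking matters, not the offset;
* a three-round range-refining random search maximizing the sum over targets
  of the Pearson correlation between −E and GDT-TS. Each round samples
  uniformly within per-weight ranges; the next round's range is the envelope
  of the round's top combinations, with a ×10 boundary expansion (or lower
  boundary shrink) when the top combinations pin against a range edge. The
  final weights are the mean of the last round's top combinations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .features import FEATURE_NAMES
from .scoring import TargetPool, WeightVector

__all__ = ["SearchConfig", "FitResult", "objective", "random_search",
           "fit_linear_regression", "per_feature_fit_mse"]

_EPS = 1e-12


@dataclass
class SearchConfig:
    """Protocol parameters of the range-refining random search."""

    n_rounds: int = 3
    steps_per_round: int = 10_000
    top_for_range: int = 100
    top_for_final: int = 50
    boundary_factor: float = 10.0
    initial_range: tuple[float, float] = (0.0, 1.0)
    seed: int = 0
    #: fraction of the range width within which the top combinations count as
    #: pinned against a boundary
    boundary_tol: float = 0.01

    def __post_init__(self) -> None:
        if min(self.n_rounds, self.steps_per_round,
               self.top_for_range, self.top_for_final) < 1:
            raise ValueError("all search counts must be at least 1")
        if not (self.top_for_final <= self.top_for_range <= self.steps_per_round):
            raise ValueError(
                "need top_for_final <= top_for_range <= steps_per_round")
        if self.boundary_factor <= 1:
            raise ValueError("boundary_factor must exceed 1")
        lo, hi = self.initial_range
        if not (0 <= lo < hi):
            raise ValueError("initial_range must satisfy 0 <= lo < hi")


@dataclass
class FitResult:
    """Outcome of a weight fit."""

    weights: WeightVector
    objective: float
    method: str
    per_feature_mse: Optional[dict[str, float]] = None
    trace: list[dict] = field(default_factory=list)
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# Objective

def _prepare_pools(pools: Sequence[TargetPool]) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per usable pool: (feature matrix, standardized quality vector)."""
    prepared = []
    for pool in pools:
        labelled = pool.labelled()
        if len(labelled) < 3:
            warnings.warn(
                f"pool {pool.target_id!r} has fewer than 3 labelled models; skipped")
            continue
        q = np.array([m.gdt_ts for m in labelled.models], dtype=float)
        sd = q.std()
        if sd < _EPS:
            warnings.warn(
                f"pool {pool.target_id!r} has constant quality; contributes 0")
            continue
        F = labelled.feature_matrix()
        if F.std(axis=0).max() < _EPS:
            warnings.warn(
                f"pool {pool.target_id!r} has constant features; unusable")
            continue
        prepared.append((F, (q - q.mean()) / sd))
    if not prepared:
        raise ValueError("no usable labelled pool")
    return prepared


def _batch_objective(W: np.ndarray,
                     prepared: list[tuple[np.ndarray, np.ndarray]],
                     warn_constant: bool = False) -> np.ndarray:
    """Σ_targets corr(−E, quality) for each weight row of W (shape m×6)."""
    total = np.zeros(W.shape[0])
    for F, zq in prepared:
        E = F @ W.T                        # n × m
        Ec = E - E.mean(axis=0)
        sd = np.sqrt((Ec ** 2).mean(axis=0))
        ok = sd > _EPS
        if warn_constant and not ok.all():
            warnings.warn("constant total score in a pool; contributes 0")
        corr = np.zeros(W.shape[0])
        corr[ok] = (zq @ Ec[:, ok]) / (len(zq) * sd[ok])
        total -= corr                      # corr(−E, q) = −corr(E, q)
    return total


def objective(w: WeightVector, pools: Sequence[TargetPool]) -> float:
    """Sum over targets of Pearson corr(−E(w), GDT-TS)."""
    prepared = _prepare_pools(pools)
    return float(_batch_objective(w.as_array()[None, :], prepared,
                                  warn_constant=True)[0])


# ---------------------------------------------------------------------------
# Random search

def random_search(pools: Sequence[TargetPool],
                  config: Optional[SearchConfig] = None) -> FitResult:
    """Range-refining uniform random search over the six weights.

    Deterministic for a fixed seed; the best combination found so far is
    carried into every subsequent round's candidate set, so the best recorded
    objective never decreases across rounds.
    """
    config = config or SearchConfig()
    prepared = _prepare_pools(pools)
    rng = np.random.default_rng(config.seed)
    lo = np.full(6, config.initial_range[0], dtype=float)
    hi = np.full(6, config.initial_range[1], dtype=float)
    best_w: Optional[np.ndarray] = None
    best_obj = -np.inf
    trace: list[dict] = []
    order = None
    W = None

    for round_idx in range(config.n_rounds):
        W = lo + (hi - lo) * rng.random((config.steps_per_round, 6))
        if best_w is not None:
            W = np.vstack([W, best_w])
        obj = _batch_objective(W, prepared)
        order = np.argsort(-obj, kind="stable")
        if obj[order[0]] > best_obj:
            best_obj = float(obj[order[0]])
            best_w = W[order[0]].copy()

        top = W[order[:config.top_for_range]]
        env_lo, env_hi = top.min(axis=0), top.max(axis=0)
        width = hi - lo
        pinned_hi = env_hi >= hi - config.boundary_tol * width
        pinned_lo = env_lo <= lo + config.boundary_tol * width
        next_hi = np.where(pinned_hi, hi * config.boundary_factor, env_hi)
        next_lo = np.where(pinned_lo, lo / config.boundary_factor, env_lo)

        trace.append({
            "round": round_idx + 1,
            "range_lo": lo.copy(), "range_hi": hi.copy(),
            "envelope_lo": env_lo, "envelope_hi": env_hi,
            "pinned_lo": pinned_lo, "pinned_hi": pinned_hi,
            "best_objective": best_obj,
        })
        lo, hi = next_lo, next_hi

    final_top = W[order[:config.top_for_final]]
    final_w = final_top.mean(axis=0)
    final_obj = float(_batch_objective(final_w[None, :], prepared)[0])
    return FitResult(weights=WeightVector.from_array(final_w),
                     objective=final_obj, method="random_search",
                     trace=trace, seed=config.seed)


# ---------------------------------------------------------------------------
# Linear regression

def _pooled_design(pools: Sequence[TargetPool]) -> tuple[np.ndarray, np.ndarray]:
    prepared = []
    for pool in pools:
        labelled = pool.labelled()
        if len(labelled) < 3:
            warnings.warn(
                f"pool {pool.target_id!r} has fewer than 3 labelled models; skipped")
            continue
        prepared.append((labelled.feature_matrix(),
                         np.array([m.gdt_ts for m in labelled.models])))
    if not prepared:
        raise ValueError("no usable labelled pool")
    X = np.vstack([F for F, _ in prepared])
    y = np.concatenate([q for _, q in prepared])
    return X, y


def _collinear_features(X: np.ndarray) -> list[str]:
    """Names of feature columns beyond the numerical rank (QR pivoting)."""
    from scipy.linalg import qr

    Xc = X - X.mean(axis=0)
    _, R, piv = qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xc.shape) * np.finfo(float).eps if diag.max() > 0 else 0
    rank = int((diag > tol).sum())
    return sorted(FEATURE_NAMES[k] for k in piv[rank:])


def fit_linear_regression(pools: Sequence[TargetPool]) -> FitResult:
    """OLS of GDT-TS on the pooled six features; intercept fitted, then dropped.

    The returned weights are the negated slopes, so that the score E = Σ w·f
    decreases as predicted quality increases (lower E = better), matching the
    ranking convention of the random search.
    """
    X, y = _pooled_design(pools)
    design = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(design) < 7:
        bad = _collinear_features(X)
        raise ValueError(f"design matrix is rank deficient; "
                         f"collinear features: {bad}")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    weights = WeightVector.from_array(-beta[1:])
    return FitResult(weights=weights,
                     objective=objective(weights, pools),
                     method="linear_regression",
                     per_feature_mse=per_feature_fit_mse(pools))


def per_feature_fit_mse(pools: Sequence[TargetPool]) -> dict[str, float]:
    """Mean squared error of a one-feature (slope + intercept) fit of GDT-TS."""
    X, y = _pooled_design(pools)
    out: dict[str, float] = {}
    for k, name in enumerate(FEATURE_NAMES):
        x = X[:, k]
        if x.std() < _EPS:
            warnings.warn(f"feature {name!r} is constant; intercept-only fit")
            out[name] = float(np.mean((y - y.mean()) ** 2))
            continue
        fit = stats.linregress(x, y)
        resid = y - (fit.intercept + fit.slope * x)
        out[name] = float(np.mean(resid ** 2))
    return out
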