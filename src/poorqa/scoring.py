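"""Linear combination of the six features into a total score E, and ranking.

E = ω_dope·E_dope + ω_goap·E_goap + ω_ssh·E_ss_h + ω_sse·E_ss_e
    + ω_sa·E_sa + ω_contact·E_contact

Lower E is better: the potentials are more negative for better models and
every penalty term shrinks toward 0 as the model improves, so with
non-negative weights the best model minimizes E. Weights are stored keyed by
feature name, never by position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import FEATURE_NAMES, FeatureVector

__all__ = ["WeightVector", "PUBLISHED_WEIGHTS", "TargetPool", "PoolModel",
           "combine", "rank_pool", "select"]


@dataclass(frozen=True)
class WeightVector:
    """The six feature weights, keyed by feature name."""

    dope: float
    goap: float
    ss_h: float
    ss_e: float
    sa: float
    contact: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in FEATURE_NAMES}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "WeightVector":
        missing = set(FEATURE_NAMES) - set(d)
        if missing:
            raise ValueError(f"missing weights for {sorted(missing)}")
        return cls(**{name: float(d[name]) for name in FEATURE_NAMES})

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "WeightVector":
        v = list(map(float, values))
        if len(v) != 6:
            raise ValueError("weight vector needs exactly 6 values")
        return cls(*v)


#: Published default weights of the method (fitted on CASP12 decoy pools).
PUBLISHED_WEIGHTS = WeightVector(dope=4.96, goap=0.4, ss_h=76.5, ss_e=65.5,
                             sa=70.65, contact=168.16)


@dataclass
class PoolModel:
    """One decoy of a target: its features plus optional quality labels."""

    model_id: str
    features: FeatureVector
    gdt_ts: Optional[float] = None
    tm_score: Optional[float] = None


@dataclass
class TargetPool:
    """All decoys of one target."""

    target_id: str
    models: list[PoolModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.model_id for m in self.models]
        if len(set(ids)) != len(ids):
            raise ValueError(f"pool {self.target_id!r} has duplicate model ids")

    def __len__(self) -> int:
        return len(self.models)

    def feature_matrix(self) -> np.ndarray:
        return np.array([m.features.as_array() for m in self.models])

    def labelled(self) -> "TargetPool":
        """Sub-pool of models that carry a GDT-TS label."""
        return TargetPool(self.target_id,
                          [m for m in self.models if m.gdt_ts is not None])


def combine(f: FeatureVector, w: WeightVector) -> float:
    """Total score E — the weighted sum of the six features (lower is better)."""
    return float(f.as_array() @ w.as_array())


def rank_pool(pool: TargetPool, w: WeightVector) -> list[PoolModel]:
    """Models ordered by ascending E; ties broken by model_id."""
    if len(pool) == 0:
        raise ValueError(f"pool {pool.target_id!r} is empty")
    return sorted(pool.models, key=lambda m: (combine(m.features, w), m.model_id))


def select(pool: TargetPool, w: WeightVector, k: int = 5
           ) -> tuple[str, list[str]]:
    """Top-1 model id and the ids of the first k ranked models."""
    ranked = rank_pool(pool, w)
    top = [m.model_id for m in ranked[:k]]
    return top[0], top
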